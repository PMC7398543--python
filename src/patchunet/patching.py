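"""Patch tiling/stitching and label-map <-> one-hot target conversion.

A canvas slice is decomposed into fixed-size square patches either as an
exhaustive non-overlapping grid (the default pipeline) or as a strided
sliding window (the overlapping comparison harness).  The
:class:`PatchGrid` records offsets and canvas shape so the decomposition is
exactly invertible.  Patch order is row-major by offset throughout, so
serialized grids are reproducible byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .preprocess import DEFAULT_N_CLASSES, SliceImage

DEFAULT_PATCH = 128
#: fixed channel order for one-hot targets
CLASS_NAMES = ("background", "CSF", "GM", "WM")


@dataclass
class PatchGrid:
    """Ordered patches + offsets: the invertible record needed to stitch."""

    patches: list[np.ndarray]
    offsets: list[tuple[int, int]]
    canvas_shape: tuple[int, int]
    patch_size: int
    overlapping: bool = False
    stride: int | None = None
    label_patches: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.stride is None:
            self.stride = self.patch_size
        h, w = self.canvas_shape
        p = self.patch_size
        for r, c in self.offsets:
            if r + p > h or c + p > w:
                raise ValidationError(f"offset ({r},{c}) overflows canvas {h}x{w}")

    def __len__(self) -> int:
        return len(self.patches)

    def save(self, directory: str | Path) -> None:
        """Serialize as one ``.npy`` per patch plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, patch in enumerate(self.patches):
            np.save(directory / f"patch_{i:05d}.npy", patch)
        if self.label_patches is not None:
            for i, patch in enumerate(self.label_patches):
                np.save(directory / f"label_{i:05d}.npy", patch)
        manifest = {
            "offsets": [list(o) for o in self.offsets],
            "canvas_shape": list(self.canvas_shape),
            "patch_size": self.patch_size,
            "overlapping": self.overlapping,
            "stride": self.stride,
            "n_patches": len(self.patches),
            "has_labels": self.label_patches is not None,
            "ordering": "row-major",
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "PatchGrid":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        n = manifest["n_patches"]
        patches = [np.load(directory / f"patch_{i:05d}.npy") for i in range(n)]
        labels = None
        if manifest["has_labels"]:
            labels = [np.load(directory / f"label_{i:05d}.npy") for i in range(n)]
        return cls(
            patches=patches,
            offsets=[tuple(o) for o in manifest["offsets"]],
            canvas_shape=tuple(manifest["canvas_shape"]),
            patch_size=manifest["patch_size"],
            overlapping=manifest["overlapping"],
            stride=manifest["stride"],
            label_patches=labels,
        )


def _grid_offsets(h: int, w: int, p: int, stride: int, include_edges: bool) -> list[tuple[int, int]]:
    rows = list(range(0, h - p + 1, stride))
    cols = list(range(0, w - p + 1, stride))
    if include_edges:
        if rows[-1] != h - p:
            rows.append(h - p)
        if cols[-1] != w - p:
            cols.append(w - p)
    return [(r, c) for r in rows for c in cols]


def split_nonoverlapping(s: SliceImage, patch_size: int = DEFAULT_PATCH) -> PatchGrid:
    """Tile a slice into an exhaustive grid of disjoint P x P patches.

    Every pixel lands in exactly one patch; the canvas must be divisible by
    the patch size (a 256 canvas with P=128 gives the 2x2 grid of the default
    pipeline).
    """
    h, w = s.shape
    if h % patch_size or w % patch_size:
        raise ValidationError(
            f"canvas {h}x{w} not divisible by patch size {patch_size}"
        )
    offsets = _grid_offsets(h, w, patch_size, patch_size, include_edges=False)
    patches = [s.pixels[r : r + patch_size, c : c + patch_size] for r, c in offsets]
    label_patches = None
    if s.labels is not None:
        label_patches = [
            s.labels[r : r + patch_size, c : c + patch_size] for r, c in offsets
        ]
    return PatchGrid(
        patches=patches,
        offsets=offsets,
        canvas_shape=(h, w),
        patch_size=patch_size,
        overlapping=False,
        label_patches=label_patches,
    )


def split_overlapping(
    s: SliceImage,
    patch_size: int = DEFAULT_PATCH,
    stride: int = 8,
    include_edges: bool = False,
) -> PatchGrid:
    """Strided sliding-window tiling (the overlapping-baseline harness).

    Offsets enumerate every multiple of ``stride`` whose patch fits on the
    canvas, row-major.  Trailing positions where the stride does not divide
    ``H - P`` are dropped unless ``include_edges`` is set.
    """
    h, w = s.shape
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    if patch_size > h or patch_size > w:
        raise ValidationError(f"patch size {patch_size} exceeds canvas {h}x{w}")
    offsets = _grid_offsets(h, w, patch_size, stride, include_edges)
    patches = [s.pixels[r : r + patch_size, c : c + patch_size] for r, c in offsets]
    label_patches = None
    if s.labels is not None:
        label_patches = [
            s.labels[r : r + patch_size, c : c + patch_size] for r, c in offsets
        ]
    return PatchGrid(
        patches=patches,
        offsets=offsets,
        canvas_shape=(h, w),
        patch_size=patch_size,
        overlapping=True,
        stride=stride,
        label_patches=label_patches,
    )


def stitch(grid: PatchGrid, patches: list[np.ndarray] | None = None) -> np.ndarray:
    """Reassemble patches onto the canvas.

    Non-overlapping grids paste each patch at its offset (exact inverse of
    :func:`split_nonoverlapping`).  Overlapping grids average the covering
    patches per pixel — for C-channel score patches the mean is taken per
    channel, so a later argmax sees the averaged class scores.

    ``patches`` may substitute the grid's own patches (e.g. model outputs),
    and may carry a trailing channel axis.
    """
    if patches is None:
        patches = grid.patches
    if len(patches) != len(grid.offsets):
        raise ValidationError("patch count does not match grid offsets")
    h, w = grid.canvas_shape
    p = grid.patch_size
    extra = patches[0].shape[2:] if patches[0].ndim > 2 else ()
    if not grid.overlapping:
        covered = np.zeros((h, w), dtype=bool)
        for r, c in grid.offsets:
            covered[r : r + p, c : c + p] = True
        if not covered.all():
            raise ValidationError("non-overlapping offsets do not cover the canvas")
        out = np.zeros((h, w) + extra, dtype=np.result_type(*patches))
        for patch, (r, c) in zip(patches, grid.offsets):
            out[r : r + p, c : c + p] = patch
        return out
    acc = np.zeros((h, w) + extra, dtype=np.float64)
    counts = np.zeros((h, w), dtype=np.float64)
    for patch, (r, c) in zip(patches, grid.offsets):
        acc[r : r + p, c : c + p] += patch
        counts[r : r + p, c : c + p] += 1
    if (counts == 0).any():
        raise ValidationError("overlapping offsets leave uncovered pixels")
    return acc / counts.reshape((h, w) + (1,) * len(extra))


def encode_onehot(labels: np.ndarray, n_classes: int = DEFAULT_N_CLASSES) -> np.ndarray:
    """Convert an integer class map to a (H, W, C) stack of binary indicator maps.

    Channel order is fixed as (background, CSF, GM, WM) for C=4; per-pixel
    channel sums are exactly 1.
    """
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValidationError(
            f"label value {int(labels.max())} outside [0, {n_classes})"
        )
    return (labels[..., None] == np.arange(n_classes)).astype(np.float64)


def decode_onehot(scores: np.ndarray) -> np.ndarray:
    """Per-pixel argmax over the trailing channel axis of a score stack.

    Ties break toward the lowest class index (numpy argmax), which favors
    background on exact ties — deterministic by construction.
    """
    scores = np.asarray(scores)
    if scores.ndim != 3:
        raise ValidationError(f"expected (H, W, C) scores, got shape {scores.shape}")
    return np.argmax(scores, axis=-1).astype(np.uint8)
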