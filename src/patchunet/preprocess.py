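"""Volume and slice I/O, plane extraction, canvas padding, and slice selection.

A :class:`Volume` pairs a 3D intensity grid with an optional integer label
grid (0=background, 1=CSF, 2=GM, 3=WM by convention).  Each array axis is
named after the anatomical plane it slices: indexing along the axis named
``"axial"`` yields axial slices, and so on.  2D slices are carried as
:class:`SliceImage` objects that remember how they were padded so that
predictions can be reported in native geometry.

All indices are 0-based, arrays are (row, col) with row 0 at the top, and
ranges are half-open.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError, ValidationError

PLANES = ("axial", "coronal", "sagittal")
DEFAULT_CANVAS = 256
DEFAULT_N_CLASSES = 4

PadRecord = tuple[int, int, int, int]  # (top, bottom, left, right)


@dataclass
class Volume:
    """3D intensity grid with an optional voxel-label companion grid.

    Parameters
    ----------
    intensities
        3D array of scalars in arbitrary physical units.
    labels
        Optional 3D integer array of the same shape with values in
        ``{0 .. n_classes-1}``.
    axis_names
        Ordered triple naming the anatomical plane each array axis slices.
    subject_id
        Free-form identifier carried through the pipeline.
    n_classes
        Number of tissue classes including background (default 4).
    """

    intensities: np.ndarray
    labels: np.ndarray | None = None
    axis_names: tuple[str, str, str] = PLANES
    subject_id: str = ""
    n_classes: int = DEFAULT_N_CLASSES

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValidationError(
                f"intensities must be 3D, got shape {self.intensities.shape}"
            )
        if len(set(self.axis_names)) != 3 or not set(self.axis_names) <= set(PLANES):
            raise ValidationError(
                f"axis_names must be a permutation of {PLANES}, got {self.axis_names}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.intensities.shape:
                raise ValidationError(
                    f"label shape {self.labels.shape} does not match "
                    f"intensity shape {self.intensities.shape}"
                )
            bad = self.labels[(self.labels < 0) | (self.labels >= self.n_classes)]
            if bad.size:
                raise ValidationError(
                    f"label value {int(bad.flat[0])} outside [0, {self.n_classes})"
                )
            self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class SliceImage:
    """A single 2D slice, optionally labelled, extracted along a named plane."""

    pixels: np.ndarray
    labels: np.ndarray | None = None
    plane: str = "axial"
    index: int = 0
    pad_record: PadRecord | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError(f"slice pixels must be 2D, got {self.pixels.shape}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.pixels.shape:
                raise ValidationError("slice labels must match pixel shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def load_volume(
    path: str | Path,
    label_path: str | Path | None = None,
    axis_names: tuple[str, str, str] = PLANES,
    n_classes: int = DEFAULT_N_CLASSES,
) -> Volume:
    """Load a NIfTI (``.nii``/``.nii.gz``) or Analyze (``.img``/``.hdr``) volume.

    Arrays are read in stored axis order; ``axis_names`` declares which
    anatomical plane each stored axis slices (no orientation inference is
    attempted).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such volume file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise FormatError(f"cannot read {path} as NIfTI/Analyze: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    labels = None
    if label_path is not None:
        label_path = Path(label_path)
        if not label_path.exists():
            raise FormatError(f"no such label file: {label_path}")
        limg = nib.load(str(label_path))
        labels = np.asanyarray(limg.dataobj)
        if labels.ndim == 4 and labels.shape[3] == 1:
            labels = labels[..., 0]
        labels = np.rint(labels).astype(np.int64)
    return Volume(
        intensities=np.asarray(data, dtype=np.float64),
        labels=labels,
        axis_names=axis_names,
        subject_id=path.stem.replace(".nii", ""),
        n_classes=n_classes,
    )


def save_volume(vol: Volume, path: str | Path, label_path: str | Path | None = None) -> None:
    """Write a volume (and optionally its labels) as NIfTI with identity affine."""
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(vol.intensities.astype(np.float32), affine), str(path))
    if label_path is not None:
        if vol.labels is None:
            raise ValidationError("volume has no labels to save")
        nib.save(nib.Nifti1Image(vol.labels.astype(np.uint8), affine), str(label_path))


def extract_slices(vol: Volume, plane: str) -> list[SliceImage]:
    """Return one :class:`SliceImage` per index along the named plane's axis.

    The two in-plane axes keep their stored order, so a 208x176x176 volume
    whose last axis is axial yields 176 slices of 208x176.
    """
    if plane not in PLANES:
        raise ValidationError(f"unknown plane {plane!r}; expected one of {PLANES}")
    if plane not in vol.axis_names:
        raise ValidationError(f"volume axes {vol.axis_names} do not include {plane!r}")
    axis = vol.axis_names.index(plane)
    moved = np.moveaxis(vol.intensities, axis, 0)
    lmoved = np.moveaxis(vol.labels, axis, 0) if vol.labels is not None else None
    return [
        SliceImage(
            pixels=moved[i],
            labels=None if lmoved is None else lmoved[i],
            plane=plane,
            index=i,
        )
        for i in range(moved.shape[0])
    ]


def restack_slices(slices: list[SliceImage], vol: Volume) -> Volume:
    """Inverse of :func:`extract_slices`: rebuild a volume in native axis order."""
    if not slices:
        raise ValidationError("cannot restack an empty slice list")
    plane = slices[0].plane
    axis = vol.axis_names.index(plane)
    stack = np.stack([s.pixels for s in slices], axis=0)
    intensities = np.moveaxis(stack, 0, axis)
    labels = None
    if all(s.labels is not None for s in slices):
        labels = np.moveaxis(np.stack([s.labels for s in slices], axis=0), 0, axis)
    return dataclasses.replace(vol, intensities=intensities, labels=labels)


def pad_to_canvas(s: SliceImage, canvas: int = DEFAULT_CANVAS) -> SliceImage:
    """Center a slice on a square ``canvas x canvas`` grid of zeros.

    Odd remainders place the extra row at the bottom and the extra column at
    the right.  Labels are padded with class 0 (background).  Cropping is
    never silent: an oversized slice raises.
    """
    h, w = s.shape
    if h > canvas or w > canvas:
        raise ValidationError(
            f"slice {h}x{w} exceeds canvas {canvas}; refusing to crop"
        )
    top = (canvas - h) // 2
    bottom = canvas - h - top
    left = (canvas - w) // 2
    right = canvas - w - left
    pixels = np.pad(s.pixels, ((top, bottom), (left, right)))
    labels = None
    if s.labels is not None:
        labels = np.pad(s.labels, ((top, bottom), (left, right)))
    return SliceImage(
        pixels=pixels,
        labels=labels,
        plane=s.plane,
        index=s.index,
        pad_record=(top, bottom, left, right),
    )


def unpad(s: SliceImage) -> SliceImage:
    """Undo :func:`pad_to_canvas` using the stored pad record."""
    if s.pad_record is None:
        raise ValidationError("slice has no pad_record; cannot unpad")
    top, bottom, left, right = s.pad_record
    h, w = s.shape
    pixels = s.pixels[top : h - bottom, left : w - right]
    labels = None
    if s.labels is not None:
        labels = s.labels[top : h - bottom, left : w - right]
    return SliceImage(
        pixels=pixels, labels=labels, plane=s.plane, index=s.index, pad_record=None
    )


def save_slice_png(s: SliceImage, path: str | Path, windowed: bool = True) -> None:
    """Export a slice as an 8-bit grayscale PNG.

    ``windowed`` rescales the slice's own intensity range to 0..255 (a
    constant slice becomes all black); otherwise values are clipped to
    [0, 255] as-is.  Label maps can be exported by wrapping them in a
    SliceImage — with 4 classes the coding survives the round trip.
    """
    import imageio.v3 as iio

    x = s.pixels.astype(np.float64)
    if windowed:
        lo, hi = x.min(), x.max()
        x = np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo) * 255
    iio.imwrite(Path(path), np.clip(x, 0, 255).astype(np.uint8))


def normalize_intensity(vol: Volume, mode: str = "minmax") -> Volume:
    """Rescale volume intensities; labels are untouched.

    ``minmax`` maps the volume's range onto [0, 1]; ``zscore`` maps to zero
    mean and unit variance; ``none`` is the identity.  A constant volume maps
    to all zeros under both rescaling modes.
    """
    if mode == "none":
        return vol
    x = vol.intensities.astype(np.float64)
    if mode == "minmax":
        lo, hi = x.min(), x.max()
        out = np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)
    elif mode == "zscore":
        sd = x.std()
        out = np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd
    else:
        raise ValidationError(f"unknown normalization mode {mode!r}")
    return dataclasses.replace(vol, intensities=out)


def select_training_slices(n_slices: int, count: int = 48, interval: int = 3) -> list[int]:
    """Pick ``count`` evenly spaced slice indices, centered in the stack.

    The window spans ``(count-1)*interval + 1`` slices and starts at
    ``floor((n_slices - 1 - (count-1)*interval) / 2)``, so it includes both
    central (information-rich) and non-central slices.  Deterministic.
    """
    if count < 1 or interval < 1:
        raise ValidationError("count and interval must be >= 1")
    span = (count - 1) * interval
    if span >= n_slices:
        feasible = (n_slices - 1) // interval + 1
        raise ValidationError(
            f"cannot take {count} slices at interval {interval} from {n_slices}; "
            f"at most {feasible} fit"
        )
    start = (n_slices - 1 - span) // 2
    return list(range(start, start + span + 1, interval))
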