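"""Dataset assembly, SGD training, and patch-stitched prediction.

Training follows the published recipe: plain stochastic gradient descent
with momentum 0.99 and learning rate 0.001, categorical cross-entropy
against 4-channel one-hot targets, no data augmentation.  Prediction splits
each canvas slice into patches, runs the network per patch, stitches the
class-score patches back onto the canvas and takes the per-pixel argmax.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import patching, preprocess
from .errors import ValidationError
from .network import UNet
from .nnops import categorical_crossentropy
from .patching import decode_onehot, encode_onehot, split_nonoverlapping, split_overlapping, stitch
from .preprocess import SliceImage, Volume


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the published recipe)."""

    learning_rate: float = 0.001
    momentum: float = 0.99
    loss: str = "categorical_crossentropy"
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    init: str = "he_normal"
    shuffle: bool = True
    # early stopping is off by default; when enabled, val_fraction of the
    # pairs is held out and training stops after `patience` epochs without
    # validation-loss improvement
    early_stopping: bool = False
    val_fraction: float = 0.1
    patience: int = 10

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValidationError("learning_rate must be >= 0")
        if not 0 <= self.momentum < 1:
            raise ValidationError("momentum must be in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValidationError("batch_size and epochs must be >= 1")


@dataclass
class TrainReport:
    """Per-epoch training trace plus the exact configuration that produced it."""

    losses: list[float] = field(default_factory=list)
    accuracies: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    epochs: int = 0
    seed: int = 0
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass
class PipelineConfig:
    """Preprocessing + patching settings shared by training and prediction."""

    plane: str = "axial"
    canvas_size: int = 256
    patch_size: int = 128
    normalize: str = "minmax"
    slice_count: int = 48
    slice_interval: int = 3
    mode: str = "nonoverlap"  # or "overlap"
    stride: int = 8
    include_edges: bool = False


def make_training_set(
    volumes: list[Volume], cfg: PipelineConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Build ordered (image patch, one-hot target patch) pairs.

    Pipeline per volume: intensity normalization -> plane slices ->
    centered slice selection -> zero-padding to the canvas -> non-overlapping
    split of image and labels alike -> one-hot encoding of label patches.
    Pair order is deterministic given the config and input order.
    """
    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    for vol in volumes:
        if vol.labels is None:
            raise ValidationError(
                f"volume {vol.subject_id!r} has no labels; cannot train on it"
            )
        vol = preprocess.normalize_intensity(vol, cfg.normalize)
        slices = preprocess.extract_slices(vol, cfg.plane)
        idx = preprocess.select_training_slices(
            len(slices), cfg.slice_count, cfg.slice_interval
        )
        for i in idx:
            padded = preprocess.pad_to_canvas(slices[i], cfg.canvas_size)
            grid = split_nonoverlapping(padded, cfg.patch_size)
            for img, lab in zip(grid.patches, grid.label_patches):
                pairs.append((img, encode_onehot(lab)))
    if not pairs:
        raise ValidationError("empty training set")
    return pairs


def train(model: UNet, data: list[tuple[np.ndarray, np.ndarray]],
          cfg: TrainConfig, augment=None) -> tuple[UNet, TrainReport]:
    """SGD-with-momentum training; returns the model and its loss trace.

    Deterministic given ``cfg.seed``: shuffling uses its own generator and
    all kernels are plain NumPy, so two runs with the same seed produce
    identical weights and loss traces.

    ``augment`` is an optional hook ``(rng, xb, yb) -> (xb, yb)`` applied
    per batch; it defaults to off and none is supplied anywhere in the
    package's own pipelines.
    """
    if not data:
        raise ValidationError("no training data")
    n_classes = model.spec.n_classes
    if data[0][1].shape[-1] != n_classes:
        raise ValidationError(
            f"target channels {data[0][1].shape[-1]} != model classes {n_classes}"
        )
    x = np.stack([p[0] for p in data]).astype(model.dtype)[..., None]
    y = np.stack([p[1] for p in data]).astype(model.dtype)
    rng = np.random.default_rng(cfg.seed)
    x_val = y_val = None
    if cfg.early_stopping:
        n_val = max(1, int(round(len(data) * cfg.val_fraction)))
        if n_val >= len(data):
            raise ValidationError("validation split leaves no training data")
        split = rng.permutation(len(data))
        x_val, y_val = x[split[:n_val]], y[split[:n_val]]
        x, y = x[split[n_val:]], y[split[n_val:]]
    velocity = {
        name: {k: np.zeros_like(v) for k, v in p.items()}
        for name, p in model.params.items()
    }
    report = TrainReport(seed=cfg.seed, config=dataclasses.asdict(cfg))
    n = len(x)
    best_val = np.inf
    since_best = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        epoch_loss = 0.0
        epoch_correct = 0
        epoch_pixels = 0
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            xb, yb = x[sel], y[sel]
            if augment is not None:
                xb, yb = augment(rng, xb, yb)
            probs = model.forward(xb, cache=True)
            loss = categorical_crossentropy(probs, yb)
            if not np.isfinite(loss):
                raise ValidationError(
                    f"non-finite loss at epoch {epoch}: lr={cfg.learning_rate}, "
                    f"momentum={cfg.momentum}"
                )
            n_pix = np.prod(probs.shape[:-1])
            grads = model.backward((probs - yb) / n_pix)
            for name, g in grads.items():
                for k in ("W", "b"):
                    v = velocity[name][k]
                    v *= cfg.momentum
                    v -= cfg.learning_rate * g[k].astype(model.dtype)
                    model.params[name][k] += v
            epoch_loss += loss * len(sel)
            epoch_correct += int(
                (probs.argmax(-1) == yb.argmax(-1)).sum()
            )
            epoch_pixels += int(n_pix)
        report.losses.append(epoch_loss / n)
        report.accuracies.append(epoch_correct / epoch_pixels)
        report.epochs = epoch + 1
        if cfg.early_stopping:
            val_loss = categorical_crossentropy(model.forward(x_val), y_val)
            report.val_losses.append(val_loss)
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
    return model, report


def predict_slice(model: UNet, s: SliceImage, cfg: PipelineConfig,
                  return_scores: bool = False) -> np.ndarray:
    """Segment one canvas slice: split -> per-patch forward -> stitch -> argmax.

    In ``overlap`` mode patches slide with ``cfg.stride`` and the stitched
    canvas holds the per-pixel mean of the covering patches' class scores,
    taken before the argmax.  With ``stride == patch_size`` this reduces
    exactly to the non-overlapping path.
    """
    if s.shape != (cfg.canvas_size, cfg.canvas_size):
        raise ValidationError(
            f"slice {s.shape} is not canvas-sized ({cfg.canvas_size}); "
            "pad it first"
        )
    if cfg.mode == "nonoverlap":
        grid = split_nonoverlapping(s, cfg.patch_size)
    elif cfg.mode == "overlap":
        grid = split_overlapping(s, cfg.patch_size, cfg.stride, cfg.include_edges)
    else:
        raise ValidationError(f"unknown prediction mode {cfg.mode!r}")
    scores = model.forward(np.stack(grid.patches))
    canvas_scores = stitch(grid, list(scores))
    labels = decode_onehot(canvas_scores)
    if return_scores:
        return labels, canvas_scores
    return labels


def class_binary_map(labels: np.ndarray, class_index: int) -> np.ndarray:
    """Binary map of one tissue class from a predicted label map."""
    return (np.asarray(labels) == class_index)


def predict_volume(model: UNet, vol: Volume, cfg: PipelineConfig) -> Volume:
    """Slice-wise prediction along ``cfg.plane``, reported in native geometry."""
    vol_n = preprocess.normalize_intensity(vol, cfg.normalize)
    slices = preprocess.extract_slices(vol_n, cfg.plane)
    out_slices = []
    for s in slices:
        padded = preprocess.pad_to_canvas(s, cfg.canvas_size)
        labels = predict_slice(model, padded, cfg)
        labelled = SliceImage(
            pixels=padded.pixels, labels=labels, plane=s.plane,
            index=s.index, pad_record=padded.pad_record,
        )
        out_slices.append(preprocess.unpad(labelled))
    pred = preprocess.restack_slices(out_slices, vol)
    return dataclasses.replace(vol, labels=pred.labels)
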