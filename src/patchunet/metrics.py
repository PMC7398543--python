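"""Segmentation evaluation: per-class Jaccard, Dice, Hausdorff, and label MSE.

For a tissue class c, the ground-truth mask I and predicted mask I' are the
pixel sets where the respective label maps equal c.  The scores are

    JI(I, I')  = |I n I'| / |I u I'|
    DSC(I, I') = 2 |I n I'| / (|I| + |I'|)
    HD(I, I')  = max( max_a min_b |b - a| , max_b min_a |a - b| )

with a in I, b in I', Euclidean distance on integer (row, col) pixel
coordinates, and HD taken over the full masks (no boundary extraction, no
percentile variant).  MSE is the mean squared difference of the integer
label maps themselves — note this depends on the class coding
(0=background, 1=CSF, 2=GM, 3=WM), so swapping class codes changes MSE but
not DSC/JI/HD.

Empty masks: when a class is absent from both maps, JI and DSC are defined
as 1 (perfect agreement on absence) and HD is undefined; both conditions
are flagged rather than silently coerced, which keeps per-slice aggregation
over sparse peripheral slices well-defined.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import directed_hausdorff

from .errors import ValidationError
from .patching import CLASS_NAMES


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")


def jaccard(i: np.ndarray, i_prime: np.ndarray) -> float:
    """|I n I'| / |I u I'|; 1.0 when both masks are empty."""
    i, i_prime = _as_bool(i), _as_bool(i_prime)
    _check_shapes(i, i_prime)
    union = np.logical_or(i, i_prime).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(i, i_prime).sum() / union)


def dice(i: np.ndarray, i_prime: np.ndarray) -> float:
    """2 |I n I'| / (|I| + |I'|); 1.0 when both masks are empty."""
    i, i_prime = _as_bool(i), _as_bool(i_prime)
    _check_shapes(i, i_prime)
    total = int(i.sum()) + int(i_prime.sum())
    if total == 0:
        return 1.0
    return float(2 * np.logical_and(i, i_prime).sum() / total)


def hausdorff(i: np.ndarray, i_prime: np.ndarray) -> float:
    """Symmetric Hausdorff distance in pixel units between two masks.

    Raises on empty masks: the distance is undefined for an empty set and
    is never silently reported as 0.
    """
    i, i_prime = _as_bool(i), _as_bool(i_prime)
    _check_shapes(i, i_prime)
    if not i.any() or not i_prime.any():
        raise ValidationError("Hausdorff distance undefined for an empty mask")
    pts_a = np.argwhere(i).astype(np.float64)
    pts_b = np.argwhere(i_prime).astype(np.float64)
    d_ab = directed_hausdorff(pts_a, pts_b)[0]
    d_ba = directed_hausdorff(pts_b, pts_a)[0]
    return float(max(d_ab, d_ba))


def mse(i: np.ndarray, i_prime: np.ndarray) -> float:
    """Mean squared difference of two integer label maps."""
    i = np.asarray(i, dtype=np.float64)
    i_prime = np.asarray(i_prime, dtype=np.float64)
    _check_shapes(i, i_prime)
    return float(np.mean((i - i_prime) ** 2))


@dataclass
class ClassScores:
    """Per-tissue-class scores with empty-mask bookkeeping."""

    dsc: float
    ji: float
    hd: float  # NaN when undefined
    hd_defined: bool
    both_empty: bool
    n_gt: int
    n_pred: int


@dataclass
class MetricReport:
    """Per-class DSC/JI/HD for the tissue classes plus whole-map MSE.

    Background (class 0) is excluded from the per-class table; only the
    tissue classes are scored, while MSE covers the full label maps.
    """

    per_class: dict[str, ClassScores]
    mse: float

    def mean_dsc(self) -> float:
        return float(np.mean([s.dsc for s in self.per_class.values()]))

    def to_dict(self) -> dict:
        return {
            "per_class": {k: dataclasses.asdict(v) for k, v in self.per_class.items()},
            "mse": self.mse,
            "mean_dsc": self.mean_dsc(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def evaluate(pred: np.ndarray, gt: np.ndarray, n_classes: int = 4,
             class_names: tuple[str, ...] = CLASS_NAMES) -> MetricReport:
    """Score a predicted label map against ground truth.

    DSC/JI/HD are computed per tissue class (classes 1..n_classes-1); MSE on
    the integer maps.  HD for a class with an empty mask on either side is
    NaN with ``hd_defined=False``.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    _check_shapes(pred, gt)
    per_class: dict[str, ClassScores] = {}
    for c in range(1, n_classes):
        mask_gt = gt == c
        mask_pred = pred == c
        both_empty = not mask_gt.any() and not mask_pred.any()
        if mask_gt.any() and mask_pred.any():
            hd = hausdorff(mask_gt, mask_pred)
            hd_defined = True
        else:
            hd = float("nan")
            hd_defined = False
        per_class[class_names[c]] = ClassScores(
            dsc=dice(mask_gt, mask_pred),
            ji=jaccard(mask_gt, mask_pred),
            hd=hd,
            hd_defined=hd_defined,
            both_empty=both_empty,
            n_gt=int(mask_gt.sum()),
            n_pred=int(mask_pred.sum()),
        )
    return MetricReport(per_class=per_class, mse=mse(pred, gt))


def aggregate(reports: list[MetricReport]) -> dict:
    """Mean and standard deviation of each metric over a set of slices.

    HD statistics are taken over the slices where HD was defined; the count
    of such slices is reported alongside.
    """
    if not reports:
        raise ValidationError("nothing to aggregate")
    out: dict = {"n_slices": len(reports), "per_class": {}}
    for cname in reports[0].per_class:
        dscs = [r.per_class[cname].dsc for r in reports]
        jis = [r.per_class[cname].ji for r in reports]
        hds = [r.per_class[cname].hd for r in reports if r.per_class[cname].hd_defined]
        out["per_class"][cname] = {
            "dsc_mean": float(np.mean(dscs)),
            "dsc_sd": float(np.std(dscs)),
            "ji_mean": float(np.mean(jis)),
            "ji_sd": float(np.std(jis)),
            "hd_mean": float(np.mean(hds)) if hds else float("nan"),
            "hd_sd": float(np.std(hds)) if hds else float("nan"),
            "hd_n_defined": len(hds),
        }
    mses = [r.mse for r in reports]
    out["mse_mean"] = float(np.mean(mses))
    out["mse_sd"] = float(np.std(mses))
    out["mean_dsc"] = float(np.mean([r.mean_dsc() for r in reports]))
    return out
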