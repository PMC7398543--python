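"""Synthetic labelled brain-like phantoms for training and testing at desk scale.

Each phantom slice is a nest of randomized ellipses mimicking T1-weighted
tissue contrast: an outer cerebrospinal-fluid rim, a gray-matter band with
sinusoidal "sulcal" boundary perturbations, a white-matter core, and CSF
"ventricle" blobs inside the core.  A head-size profile peaking at the
volume's middle makes central slices anatomy-rich and peripheral slices
sparse, so the pipeline is exercised on both.  Intensities are the tissue
mean scaled by a smooth multiplicative bias field plus Gaussian noise;
labels are the noiseless geometry, which means that with noise and bias
switched off, thresholding the intensities at the tissue-mean midpoints
recovers the labels exactly — a closed-form perfect segmenter that the
metric suite must score as flawless.

Everything is deterministic given the config seed; per-slice generators are
derived from (seed, slice position), so a volume can be regenerated
slice-by-slice or whole.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .preprocess import SliceImage, Volume


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and contrast parameters of the phantom generator.

    ``tissue_means`` follow T1 contrast ordering (background < CSF < GM <
    WM) and must be strictly increasing.  ``noise_sd`` is the additive
    Gaussian sigma on the same arbitrary intensity scale as the means;
    ``bias_amplitude`` scales a smooth multiplicative low-frequency field
    (kept mild by default, as for bias-corrected inputs); ``shape_jitter``
    scales the random boundary perturbations.
    """

    canvas: int = 256
    n_slices: int = 32
    tissue_means: tuple[float, float, float, float] = (0.0, 0.2, 0.5, 0.8)
    noise_sd: float = 0.05
    bias_amplitude: float = 0.1
    shape_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.tissue_means) != sorted(set(self.tissue_means)):
            raise ValidationError("tissue_means must be strictly increasing")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.canvas < 8:
            raise ValidationError("canvas too small")


def _slice_rng(cfg: PhantomConfig, slice_frac: float) -> np.random.Generator:
    return np.random.default_rng([cfg.seed & 0x7FFFFFFF, int(round(slice_frac * 1_000_000))])


def generate_phantom_slice(cfg: PhantomConfig, slice_frac: float) -> SliceImage:
    """One labelled phantom slice at relative position ``slice_frac`` in [0, 1].

    Head size follows ``sin(pi * slice_frac)``, so slices near 0 or 1 may
    legally contain background only.
    """
    if not 0.0 <= slice_frac <= 1.0:
        raise ValidationError("slice_frac must be in [0, 1]")
    rng = _slice_rng(cfg, slice_frac)
    n = cfg.canvas
    profile = float(np.sin(np.pi * slice_frac))
    # normalized coordinates in [-1, 1]
    coords = (np.arange(n) + 0.5) / n * 2 - 1
    yy, xx = np.meshgrid(coords, coords, indexing="ij")

    j = cfg.shape_jitter
    cy, cx = rng.uniform(-j / 2, j / 2, size=2)
    # mild ellipticity jitter
    ry = 0.80 * profile * (1 + rng.uniform(-j, j))
    rx = 0.72 * profile * (1 + rng.uniform(-j, j))
    labels = np.zeros((n, n), dtype=np.uint8)
    if profile > 1e-6:
        theta = np.arctan2(yy - cy, xx - cx)
        rho = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)
        # sulcal perturbations of the GM and WM outer boundaries
        k_gm = rng.integers(7, 12)
        k_wm = rng.integers(4, 8)
        gm_edge = 0.86 * (1 + 1.2 * j * np.sin(k_gm * theta + rng.uniform(0, 2 * np.pi)))
        wm_edge = 0.66 * (1 + 1.6 * j * np.sin(k_wm * theta + rng.uniform(0, 2 * np.pi)))
        labels[rho < 1.0] = 1  # CSF rim
        labels[rho < gm_edge] = 2  # GM band
        labels[rho < wm_edge] = 3  # WM core
        # ventricles: paired CSF blobs inside the WM core
        for sign in (-1.0, 1.0):
            vy = cy + 0.10 * profile + rng.uniform(-j / 4, j / 4)
            vx = cx + sign * (0.16 * profile) + rng.uniform(-j / 4, j / 4)
            vr_y = 0.17 * profile
            vr_x = 0.08 * profile
            vent = ((yy - vy) / max(vr_y, 1e-9)) ** 2 + (
                (xx - vx) / max(vr_x, 1e-9)
            ) ** 2 < 1.0
            labels[vent & (labels == 3)] = 1

    means = np.asarray(cfg.tissue_means)
    pixels = means[labels]
    if cfg.bias_amplitude > 0:
        fy, fx = rng.uniform(0.5, 1.5, size=2)
        py, px = rng.uniform(0, 2 * np.pi, size=2)
        bias = np.cos(np.pi * fy * yy + py) * np.cos(np.pi * fx * xx + px)
        pixels = pixels * (1 + cfg.bias_amplitude * bias)
    if cfg.noise_sd > 0:
        pixels = pixels + rng.normal(0, cfg.noise_sd, size=pixels.shape)
    return SliceImage(pixels=pixels, labels=labels, plane="axial", index=0)


def generate_phantom_volume(cfg: PhantomConfig) -> Volume:
    """Stack ``cfg.n_slices`` phantom slices into a labelled axial volume."""
    if cfg.n_slices < 2:
        raise ValidationError("n_slices must be >= 2")
    slices = [
        generate_phantom_slice(cfg, i / (cfg.n_slices - 1))
        for i in range(cfg.n_slices)
    ]
    return Volume(
        intensities=np.stack([s.pixels for s in slices]),
        labels=np.stack([s.labels for s in slices]),
        axis_names=("axial", "coronal", "sagittal"),
        subject_id=f"phantom_seed{cfg.seed}",
    )


def threshold_segment(intensities: np.ndarray,
                      tissue_means: tuple[float, ...] = PhantomConfig.tissue_means) -> np.ndarray:
    """Closed-form segmenter: assign each pixel to the class whose mean is
    nearest (equivalently, threshold at tissue-mean midpoints).

    Exact on noiseless, bias-free phantoms; a useful non-learned baseline
    otherwise.
    """
    means = np.asarray(tissue_means)
    return np.abs(np.asarray(intensities)[..., None] - means).argmin(-1).astype(np.uint8)


def make_phantom_suite(
    n_train: int, n_test: int, cfg: PhantomConfig | None = None, seed: int = 0
) -> tuple[list[Volume], list[Volume], dict]:
    """Generate disjoint train/test phantom cohorts plus a reproducibility manifest.

    Per-volume seeds are spawned from the master seed; the manifest records
    the full config and every per-volume seed, and
    :func:`volumes_from_manifest` rebuilds the cohorts bit-exactly from it.
    """
    if n_train < 1 or n_test < 1:
        raise ValidationError("n_train and n_test must be >= 1")
    cfg = cfg or PhantomConfig()
    state = np.random.SeedSequence(seed).generate_state(n_train + n_test)
    seeds = [int(s) & 0x7FFFFFFF for s in state]
    if len(set(seeds)) != len(seeds):  # vanishing probability; keep determinism
        seeds = [(s + i) & 0x7FFFFFFF for i, s in enumerate(seeds)]
    manifest = {
        "config": dataclasses.asdict(cfg),
        "master_seed": seed,
        "train_seeds": seeds[:n_train],
        "test_seeds": seeds[n_train:],
    }
    train = [
        generate_phantom_volume(dataclasses.replace(cfg, seed=s))
        for s in manifest["train_seeds"]
    ]
    test = [
        generate_phantom_volume(dataclasses.replace(cfg, seed=s))
        for s in manifest["test_seeds"]
    ]
    for i, v in enumerate(train):
        v.subject_id = f"phantom_train_{i:03d}"
    for i, v in enumerate(test):
        v.subject_id = f"phantom_test_{i:03d}"
    return train, test, manifest


def volumes_from_manifest(manifest: dict) -> tuple[list[Volume], list[Volume]]:
    """Rebuild a phantom suite exactly from its manifest."""
    cfg_kwargs = dict(manifest["config"])
    cfg_kwargs["tissue_means"] = tuple(cfg_kwargs["tissue_means"])
    base = PhantomConfig(**cfg_kwargs)
    train = [
        generate_phantom_volume(dataclasses.replace(base, seed=s))
        for s in manifest["train_seeds"]
    ]
    test = [
        generate_phantom_volume(dataclasses.replace(base, seed=s))
        for s in manifest["test_seeds"]
    ]
    return train, test
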