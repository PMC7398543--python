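# Methods

## Pipeline

A labelled subject is a 3D intensity volume with a voxel-label companion
grid coded 0=background, 1=CSF, 2=GM, 3=WM. Axes are named after the
anatomical plane they slice; the package reads volumes in stored axis order
and the caller declares the plane↔axis mapping (no orientation inference —
Analyze headers in particular are ambiguous). The training pipeline per
volume is:

1. per-volume intensity normalization (min–max to [0, 1] by default);
2. slice extraction along the configured plane;
3. centered selection of `slice_count` slices at constant `slice_interval`
   (default 48 at interval 3), so both anatomy-rich central slices and
   sparse peripheral slices enter training;
4. center zero-padding of each slice to a square canvas (default 256;
   a 208×176 slice receives 24 rows top/bottom and 40 columns left/right,
   a 128×256 slice 64 rows top/bottom), labels padded with background; odd
   remainders go to bottom/right;
5. exhaustive non-overlapping tiling into P×P patches (default 128, i.e.
   quadrants of the 256 canvas), applied identically to intensities and
   labels;
6. one-hot encoding of label patches into C binary channel maps.

Prediction inverts the pipeline: tile, run the network per patch, paste the
class-score patches back (non-overlapping) or average them per pixel
(overlapping sliding-window mode, for the comparison harness), take the
per-pixel argmax, and undo the padding so results land in native geometry.
With stride equal to the patch size the overlapping path reduces exactly to
the non-overlapping one; this equivalence is asserted bit-for-bit in the
tests. Argmax ties break toward the lowest class index — deterministic and
background-favoring.

The centered slice-selection window starts at
`floor((n_slices − 1 − (count−1)·interval) / 2)`; for 176 slices, 48 at
interval 3, that selects indices 17..158. Centering (rather than any other
anchor) is this package's choice: only the count and interval are inherent
to the protocol, and a centered window includes both central and peripheral
anatomy.

## Architecture and parameter accounting

The network is generated from a declarative `ModelSpec` (patch size P,
base filters F, pooling depth d, classes C) into a layer table that both
drives execution and yields closed-form parameter counts,
`(k²·c_in + 1)·c_out` per convolution (biases everywhere — the published
per-layer counts force them, e.g. 640 = (9+1)·64 for the first layer).
Two readings of "up-convolution" exist in the wild; the per-layer counts
admit only one: ×2 nearest-neighbor upsampling followed by a 2×2
same-padding convolution halving the channels (524,544 = (4·512+1)·256),
not a strided transpose convolution. Same padding is used throughout; for
the even 2×2 kernel the window anchors top-left (pad 0 before, 1 after), so
output size equals input size and the counts are framework-independent.
P must be divisible by 2^d; at the defaults the bottleneck is 16×16×512 and
the total is 7,696,388 parameters. The test suite asserts exact integer
equality between every table entry and the instantiated weight arrays.

## The NumPy network engine

No deep-learning framework is a dependency: convolutions are im2col matrix
products (BLAS), max-pooling caches argmax indices for its backward pass,
upsampling's adjoint sums 2×2 blocks, and the softmax/cross-entropy
gradient uses the standard `(p − y)/n_pixels` simplification. All backward
passes are exact analytic gradients, checked against central-difference
differentiation on a small double-precision network (tolerance 1e-5
absolute with a relative floor; ReLU kinks make tighter bounds
meaningless). Training runs in float32; gradient checks in float64.

Optimization is plain SGD with momentum (`v ← μv − η∇; w ← w + v`),
μ = 0.99 and η = 0.001 by default, categorical cross-entropy averaged over
batch and pixels, no class weighting, no augmentation. He-normal
initialization is the default (appropriate for ReLU stacks;
Glorot-uniform selectable). Batch size (32) and epochs (50) are
config-exposed defaults. Training is deterministic given the seed: weight
init and shuffling use separate NumPy generators and all kernels are plain
NumPy, so identical seeds reproduce identical loss traces and weights.

## Metrics

Per tissue class (background excluded from the per-class table): Jaccard
|I∩I′|/|I∪I′|, Dice 2|I∩I′|/(|I|+|I′|), and the symmetric Hausdorff
distance — Euclidean, on full pixel masks (not boundaries), in pixel units,
computed via `scipy.spatial.distance.directed_hausdorff` in both directions.
No 95th-percentile variant is offered. MSE is taken on the integer label
maps themselves, so it depends on the class coding — it is reported for
continuity with common practice, not as a coding-independent score. When a
class is absent from both maps, DSC = JI = 1 with an explicit flag (perfect
agreement on absence) and HD is NaN with `hd_defined=False`; empty masks
never silently score 0. This keeps aggregation over sparse peripheral
slices well-defined. Slice-set aggregation reports mean ± SD per metric,
with HD averaged over the slices where it was defined.

Brute-force oracles (pixel-set algebra, O(n·m) double loops) live in the
test suite only and agree with the library implementations to 1e-9.

## Phantom generator

The generator emulates the geometry the pipeline must handle, not MR
physics: per slice, an elliptical head whose radius follows
sin(π·slice_frac) (so peripheral slices carry little or no anatomy), an
outer CSF rim, a GM band and WM core with sinusoidal "sulcal" boundary
perturbations, and paired CSF ventricle blobs inside the core. Intensities
are tissue means with T1-like ordering (0.0, 0.2, 0.5, 0.8) scaled by a
smooth multiplicative bias field (amplitude 0.1 — mild, as for
bias-corrected inputs) plus Gaussian noise (σ = 0.05); labels are the
noiseless geometry. With noise and bias off, thresholding at tissue-mean
midpoints recovers the labels exactly, giving a closed-form perfect
segmenter against which the metric suite must report DSC = JI = 1, HD = 0,
MSE = 0.

What the phantoms do **not** model: anatomical realism, partial-volume
mixing at boundaries, 3D tissue continuity beyond the smooth size profile,
scanner artifacts, inter-subject variability beyond boundary jitter.
Passing the learning study therefore shows the pipeline is implemented
correctly and can fit a 4-class contrast-plus-geometry task — not that it
reaches any particular accuracy on real MRI.

Suites derive disjoint per-volume seeds from a master seed via
`numpy.random.SeedSequence`; the manifest records every seed and the full
config, and regenerating from the manifest is bit-exact.

## Desk-scale study sizes

The acceptance-level learning study uses a reduced configuration chosen to
be trainable in minutes on one CPU while exercising the full pipeline:
64-pixel canvas and patches (so one patch per slice), 8 base filters,
depth 3, a 20-train/5-test phantom cohort, one central training slice per
volume (20 patch pairs), 200 epochs at batch size 4, and three model seeds.
Held-out evaluation covers three centered slices per test volume. The
published learning rate and momentum are kept; only the scale is reduced.
Under these conditions the trained model reaches held-out mean DSC ≥ 0.85
over CSF/GM/WM for every seed and strictly beats its untrained counterpart.

## Known limitations

- The overlapping-mode patch enumeration is the standard sliding window:
  ⌊(H−P)/stride⌋+1 positions per axis (289 patches for a 256 canvas,
  P=128, stride 8). Other enumerations exist in the literature with
  incompatible counts; the grid here is documented and analytic, with an
  `include_edges` flag to force trailing anchors.
- One model is trained per plane; nothing shares weights across planes.
- MSE on label codes is coding-dependent (documented above).
- The engine is CPU-bound NumPy: fine for reduced configurations and
  correctness work, not for full-scale (F=64, 256-canvas, many-subject)
  training, which calls for a GPU framework.
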