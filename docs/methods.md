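# Methods

This note documents the models, parameters, numerical conventions, and
design choices behind `mcseg`, and what the synthetic phantom bench does
and does not establish.

## Conventions

Coordinates are `(row, col)`, 0-based, pixel centers at integer positions.
All scales and distances are in pixels unless suffixed `_mm`; the default
pixel pitch is 0.070 mm (the resolution of the mammography systems the
default parameters were calibrated for). Images are normalized to [0, 1]
by dividing by `2^bit_depth − 1` before any processing; the DoG threshold
`T_DoG = 0.006` is only meaningful on that scale, so the blob branch
refuses unnormalized input. `normalize_intensity` refuses double
application for the same reason.

## Blob branch

The scale ladder is σ_n = kⁿ σ_min with σ_min = 1.18, σ_max = 3.1 and
k = 2^(1/3) (three scales per octave — k is a free choice here; the σ
endpoints are honored exactly, and the ladder's last rung may overshoot
σ_max). The scale-normalized DoG is computed as
σ_n/(σ_{n+1} − σ_n) · (L_n − L_{n+1}) — smaller scale minus larger — which
approximates −σ²∇²L and is therefore positive at bright blob centers;
this sign is what makes a lower-bound threshold plus maxima detection
select bright structures, and what makes the downstream concavity
constraint tr(H) < 0 satisfiable at selected locations.

Maxima handling: a voxel qualifies if it is ≥ all of its up-to-26
neighbors and strictly > at least one; within a connected equal-valued
plateau only the lexicographically smallest (n, row, col) voxel is kept.
Maxima on the first and last scale planes are allowed (the σ range is
narrow; suppressing edge planes would lose the smallest MCs). Responses
must exceed T_DoG strictly. Convolutions and finite differences use
reflective borders throughout, which avoids spurious border extrema.

Overlap pruning models blobs as discs of radius √2·σ (the radius of a
binary disc whose DoG response peaks at scale σ). Candidates are processed
in descending response order; a candidate is dropped iff it overlaps an
already-kept blob of larger-or-equal σ by a fraction (lens area over the
smaller disc) strictly greater than O_DoG. The default O_DoG = 1 disables
pruning under the strict inequality.

The Hessian constraint is evaluated literally as
`tr < 0 and (det < 0 or det ≤ h_thr·tr²)`; the multiplied form avoids
dividing by tr² and is exact since tr² > 0 whenever the first clause
holds. Note that for real symmetric 2×2 matrices det/tr² ≤ 1/4 whenever
tr < 0 and det ≥ 0, so at the default h_thr = 1.4 the constraint
degenerates to pure concavity tr < 0 — a property test pins this down.
Users who want the ratio clause to bite must set h_thr < 0.25.

Object extraction takes, per blob, the 8-connected component of the
constraint mask at the blob's own scale containing the blob pixel
(8-connectivity because MCs are tiny and 4-connectivity fragments diagonal
structures). A blob whose seed pixel is constraint-background is discarded
and logged rather than reassigned to a nearby component — conservative and
deterministic. Two blobs at the same scale in the same component would
duplicate an object byte-for-byte; duplicates are collapsed keeping the
higher-response blob link.

## Proximity maps and loss

g(r) = (e^{α(1−r/ξ)} − 1)/(e^α − 1) for r ≤ ξ, else 0; α = 0 is undefined
and rejected (the α → 0 limit is the linear cone 1 − r/ξ, reproduced to
10⁻³ at α = 10⁻⁴). Defaults ξ = 10 px, α = 1. Every foreground pixel of a
filled contour is a source, so object interiors sit at P = 1 and the decay
extends ξ beyond the boundary. Since g is monotone in r, the map is
computed from the exact Euclidean distance transform to the annotation
foreground rather than an explicit max over sources; the two agree to
machine precision (tested on small masks).

The soft Dice loss uses ε = 1 in numerator and denominator; identical
binary masks score 0, as do two empty maps.

## Regression network

The decoder contract is fixed: encoder features at strides 4, 8, 16, 32;
1×1 lateral projections (no activation, as in standard feature-pyramid
decoders) to a common width; per-level 3×3 conv + ReLU; upsampling by
1/2/4/8 to the stride-4 grid; elementwise sum; spatial (channelwise)
dropout active only in training; two 3×3 convolutions; ×4 upsampling;
sigmoid. Upsampling is bilinear: nearest-neighbour quantizes the output
into 4×4 blocks, which caps attainable IoU for objects only a few pixels
wide. Inputs must be divisible by 32 and are standardized per patch to
zero mean and unit variance (mammographic brightness varies strongly
between acquisition systems, and the target is scale-free).

Two encoders are provided, both plain conv/pool stacks: `tiny`
(8/16/24/32/32 channels, the test and desk default) and `large`
(16/32/48/64/64). Pretrained classification backbones are out of scope.
The network and its reverse-mode autodiff live in `mcseg.nn` (numpy only);
gradients are verified against central finite differences in the test
suite.

Training: Adam with lr 10⁻⁴, β₁ = 0.9, β₂ = 0.999, eps 10⁻⁸, batch 8,
40 epochs at full scale; the `tiny` preset uses lr 10⁻³, batch 4,
50 epochs. The per-epoch validation metric is the mean IoU per patch
between the thresholded prediction and the patch's annotation mask
(recovered as the P = 1 level set of the proximity target), at the best
threshold from a sweep; the sweep grid is dense near 1 because
Dice-trained sigmoid outputs saturate and the informative level sets sit
near the top of (0, 1). The checkpoint with the best validation IoU over
all epochs is restored. Patch extraction uses 512-px windows at stride
480, dropping windows without annotated content; flush-to-border windows
are added where the regular grid leaves a strip uncovered. Augmentation
(flip p = 0.5, scale 0.9–1.1, translation ≤ 32 px, brightness ±10%,
contrast ×0.9–1.1, gamma 0.8–1.25 — conservative defaults, all
configurable) applies geometric transforms to image and target jointly
and photometric transforms to the image only, emitting 320×320 patches.
Full-image inference tiles with overlap and averages the overlaps.

## Fusion

Overlap fraction is |object ∩ region| / |object|; the retention rule is
boundary-inclusive (≥ o_thr, default 0.3) with a `strict` flag for the
strict-inequality reading. Retained objects keep their full pixel sets —
clipping to the region would corrupt the shape features the method exists
to provide. An all-ones region reproduces the blob branch exactly.

## Metrics

Matching: candidate (prediction, truth) pairs within 5 px centroid
distance (inclusive) or pixelwise IoU ≥ 0.3; the IoU rule requires pixel
sets on both sides (point-annotated truths match only by distance, with
the point as their centroid). Matching is greedy one-to-one in ascending
distance, audited in the tests against Hungarian assignment on small
scenes. TPR is pooled over images (ΣTP/Σtruth) and false positives are
normalized by total imaged area; pAUC integrates the linearly
interpolated, constant-extrapolated curve over 0–1 FP/cm² and divides by
the range width so a perfect detector scores 1. The bootstrap resamples
images with replacement (default B = 100, percentile 95% CI); per-image
per-threshold counts are computed once and re-pooled per replicate, which
is exactly the pooled FROC of the resampled set. The operating point
minimizes the Euclidean distance of (FP/cm², TPR) to (0, 1), ties toward
the larger threshold.

## Features and classification

Regional features treat the union mask as one (possibly disconnected)
region: area, convex-hull area, ellipse-equivalent major/minor axis
lengths, orientation of the major axis in degrees in (−90°, 90°] relative
to the row axis, eccentricity, solidity, the two eigenvalues of the
central second-moment tensor ("moments of inertia"), the seven Hu
invariant moments of the binary mask, and the MC count (8-connected
components): 17 values. Per-object features (area, axis lengths, max/min/
mean intensity on the normalized image, eccentricity) are aggregated by
mean and standard deviation (std of a single object is 0): 14 values,
31 in total. An empty segmentation yields an all-missing vector; each
cross-validation fold fits mean imputation and standardization on its
training rows only. Hu moments are computed on the binary mask (not
intensity-weighted) and intensities are the normalized ones — both choices
keep features scale-free. The classifier is gradient tree boosting
(depth 3, 200 trees, learning rate 0.1, seeded — explicit defaults, all
configurable) under patient-wise fivefold cross-validation; reports use
the trapezoidal rank-based AUC (constant scores ⇒ 0.5) and a per-fold
threshold at the observed score whose sensitivity is closest to the 0.9
target, ties toward the higher threshold.

## Phantom bench

The generator emulates what matters for this pipeline: a smooth
low-frequency background (Gaussian-filtered white noise rescaled into
[0.2, 0.6]) with independent pixel noise; small bright isotropic Gaussian
spots; short anisotropic Gaussian ridges (tubular structures); and larger
super-ellipse objects with polygonal contour annotations. Truth is the
half-maximum level set of each planted signal — unambiguous and
analytically checkable (a spot of width s has half-max radius s·√(2 ln 2)).
Objects with equivalent diameter < 10 px are annotated by their center
point, larger ones by a contour, mirroring the mixed annotation style of
clinical datasets. Object centers are kept ≥ 4·σ_max apart unless overlap
is requested. All randomness flows through explicit seeds (child seeds
spawned from a master seed per image); equal configurations reproduce
bit-identically.

The standard bench conditions are 256×256 images with ten spots of
amplitude 0.4, widths 1.5–2.5 px, and pixel noise 0.01; desk-scale
regressor experiments use twenty directly generated 64×64 phantom patches
with two spots each (generating patches directly keeps every object fully
interior, which windowed slicing of larger phantoms does not).

What the phantom does *not* model: X-ray physics (scatter, detector MTF,
quantum noise statistics), anatomic clutter such as linear fibroglandular
structures and vessels with calcified walls, pectoral muscle and skin
lines, and annotation error. Passing the bench therefore demonstrates the
correctness of the algorithms and the learnability of the regression
target under controlled conditions — not clinical-grade detection
performance; on real mammograms the false-positive burden and the
difficulty of the regression task are both substantially higher.

## Problem sizes

The test suite and the acceptance script use 20-image benches, 26–51-point
threshold sweeps, 100 bootstrap resamples, 50-epoch tiny-network training
on twenty 64×64 patches, and a 200-ROI / 40-patient synthetic cohort —
sizes chosen so the whole suite completes in about a minute on one CPU
while every stage is exercised end to end.

## Known limitations

- At the default h_thr = 1.4 the Hessian constraint reduces to tr(H) < 0
  (see above); the shape masks are correspondingly permissive, and object
  components can merge across nearby structures on smooth backgrounds.
- The greedy FROC matcher can differ from optimal assignment in rare
  dense-scene configurations (the audit tolerates < 5% on random small
  scenes; discrepancies are surfaced by the test, never hidden).
- The numpy network is CPU-bound and desk-scale; the architecture honors
  the decoder contract but is far smaller than a pretrained-backbone
  pyramid network, and no claim is made that it matches one on real data.
- `iou_per_object` is undefined for an empty truth set (returns NaN with a
  warning).
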