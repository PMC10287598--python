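# mcseg

Segmentation of breast **microcalcifications (MCs)** — tiny calcium deposits
that appear as small bright structures on 2D digital mammograms — together
with the evaluation stack and a downstream malignancy classifier. MCs matter
clinically because their morphology and distribution inform cancer
suspicion, but they are hard to delineate: most are a few pixels across,
annotations mix single-pixel location marks with pixel-wise contours, and
bright background texture produces abundant look-alikes.

`mcseg` is a library for researchers in quantitative mammography who want a
shape-accurate MC segmentation they can feed into radiomics-style analyses,
plus a fully synthetic phantom bench so every stage is testable without
clinical data.

## Method

The final segmentation is the fusion of two branches.

**Blob branch (Hessian-constrained multiscale DoG).** The image is embedded
in a Gaussian scale space L(x, y; σ) = G(σ) ∗ I over a geometric scale
ladder σ_n = kⁿ σ_min, and adjacent levels form the scale-normalized
difference of Gaussians

    DoG(x, y, n) = σ_n / (σ_{n+1} − σ_n) · (L(x, y; σ_n) − L(x, y; σ_{n+1})),

which is positive and peaked at bright blob centers. Blobs are 26-neighbor
local maxima of this (scale, row, col) volume above a threshold T_DoG, with
optional pruning of overlapping blobs (disc radius √2·σ, overlap fraction
over the smaller disc, threshold O_DoG). Each blob's *shape* is the
connected component — at the blob's own scale — of the Hessian constraint
mask

    tr(H) < 0  ∧  ( det(H) < 0  ∨  det(H)/tr(H)² ≤ h_thr ),

where H is the 2×2 Hessian of the DoG plane: both eigenvalues large and
negative (bright blob) or one large negative eigenvalue (bright tube).

**Regression branch (proximity maps).** Reference annotations — points and
filled contours alike — are mapped to a proximity function
P(x, y) = max_i g(r_i), with

    g(r) = (e^{α(1−r/ξ)} − 1) / (e^α − 1)  for r ≤ ξ,  else 0,

so P is 1 exactly on annotated pixels and decays to 0 at distance ξ
(defaults ξ = 10 px, α = 1). A fully convolutional pyramid-decoder network
(skip connections at strides 4/8/16/32, upsampling ×1/2/4/8, sum, spatial
dropout, ×4 upsampling, sigmoid) regresses P from the image, trained with
the soft Dice loss

    L_DICE(P̂, P) = 1 − (2 Σ P P̂ + ε) / (Σ (P + P̂) + ε),  ε = 1,

using Adam (40 epochs, batch 8, lr 10⁻⁴ at full scale; a `tiny` preset
exists for desk-scale work). The network here is a compact numpy
implementation with reverse-mode autodiff (`mcseg.nn`) — no GPU framework
required.

**Fusion.** Thresholding P̂ at p_thr gives a region mask of likely-MC
areas; blob objects whose overlap fraction |object ∩ region| / |object| is
at least o_thr (default 0.3) are retained with their full extent.

**Evaluation.** IoU per object (best-overlap match per reference object),
mean IoU per image (average of foreground and background class IoU), and
FROC analysis: a detection is a true positive within 5 px (0.35 mm at
0.070 mm/px) of a ground-truth object or at IoU ≥ 0.3; TPR is pooled and
false positives are normalized per cm² of imaged area; curves are
summarized by the partial AUC over 0–1 FP/cm² with a 100-resample
bootstrap CI.

**Case study tooling.** Fixed 256×256 ROIs, a 31-dimensional morphology/
intensity feature vector (17 regional + 14 aggregated per-object features),
and a gradient-boosting classifier under patient-wise fivefold
cross-validation, reported at a sensitivity-0.9 operating threshold.

## Worked example

Running `python examples/02_blob_segmentation.py`:

```
DoG maxima above T_DoG: 492 blobs
extracted objects: 76 (merged mask 47129 px)
planted objects recovered within 2 px: 10/10
```

All ten planted spots of a phantom are recovered with sub-pixel-to-2-px
centroid accuracy; the hundreds of additional maxima are background texture
— deliberate over-detection that fusion with the regression branch then
removes. And `python examples/04_train_regressor.py`:

```
training loss: 0.865 -> 0.348
mean IoU per patch, untrained: 0.010
mean IoU per patch, trained:   0.417 at p_thr 0.9999 (best epoch 11)
```

Fifty epochs on twenty 64×64 phantom patches lift the mean IoU per patch
(vs the half-maximum truth masks) from chance (~0.01) to ~0.42 at the best
swept threshold. The other scripts in `examples/` walk through phantom
generation, proximity maps and the soft Dice loss, FROC analysis, and the
feature/classification stage, each printing the quantities it computes.

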