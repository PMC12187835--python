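# Methods

This note documents the models and procedures `slnpatch` implements, the
choices made where the protocol left room, and what the synthetic
experiments do and do not show.

## Mask semantics and rasterization

Annotations arrive as labelme-style JSON polygons in H&E pixel space (the
spatial transfer from the IHC reference slide is assumed already done; no
registration is implemented). One convention is stated once and asserted
everywhere: coordinates are 0-based, x rightward, y downward; pixel (i, j)
is the half-open box [j, j+1) × [i, i+1); a pixel belongs to a polygon iff
its **center** lies inside under the **even-odd** fill rule; overlapping
polygons of the selected classes union. This makes rasterization exactly
reproducible by a brute-force point-in-polygon loop, which the test suite
exploits as an exhaustive oracle on small grids. Tumor and fibrosis are
required to be disjoint classes (how fibrosis was delimited relative to
tumor is not recoverable from the source protocol; disjointness is our
assumption, and `TumorFIB` masks are the union of the two).

Masks are stored as single-channel PNGs with values {0, 255}; mask I/O is a
bijection on binary rasters. Polygon export traces mask contours
(marching squares at level 0.5) and re-rasterizes within 0.5% of tissue
pixels; holes inside blobs are not subtracted on re-import (union-only
polygon semantics) and are absorbed by that tolerance.

## Patch datasets

Tiling uses a regular grid anchored at the slide origin with patch size 90
and stride 90 (stride 30 for `TumorExtended`); partial edge tiles are
dropped, so counts obey floor(H/s)·floor(W/s). The labeling trichotomy —
TC > 20% positive, TC = 0 negative, else excluded — is forced by the two
printed rules; patches with 0 < TC ≤ 20% enter no class. The positive rule
has deliberately no upper bound. Class balance is restored by uniform,
seeded subsampling of the majority class. The 70/30 split is stratified by
label and performed **at patch level**, reproducing the protocol's
leakage-prone design (train and test patches can come from the same slide);
whole-slide testing on disjoint slides is the honest complement and is
enforced by slide-id disjointness in the experiment driver.

`Tumor Extended` is implemented as denser re-tiling of the same slides with
a configurable stride (default 30 px, ≈9× the patch count on large slides).
The mechanism behind the original ~9.5× expansion is not stated; denser
sampling is our interpretation, since the design lists the same source
slides. `Interhospital` balances the local records, balances the
external-domain records, and subsamples both sides to a common per-class
count, giving a set that is exactly 50% local / 50% external and 50%
positive / 50% negative.

## Augmentation

Five transforms compose in a fixed order, each gated by an independent
apply probability (default 0.5): grayscale→HSV recolorization with
saturation sampled U(1, 180); Gaussian noise with mean U(0, 10); salt-and-
pepper with per-pixel corruption probability U(0, 1) (salt/pepper 50/50);
RGB channel separation; contrast/brightness `clip(αx + β)` with α ~ U(0, 10)
and β ~ U(0, 10). Interpretation notes: "grayscale followed by RGB→HSV" is
internally odd (grayscale has no saturation), so it is implemented as
grayscale → HSV with the value channel carrying luminance and the sampled
saturation (rescaled from [1, 180] to [0, 1]) applied uniformly at a fixed
hue — a recolorization strength whose scale minimum reproduces the plain
grayscale image. The Gaussian noise SD is unstated (default 5, 0–255
scale). The α range U(0, 10) includes destructive draws (α near 0); the
printed range is kept as the default and exposed in config. Augmentation is
applied on the fly during training; dataset size is unchanged.
Normalization is scaling to (0, 1) followed by per-channel standardization
with mean/SD computed over the entire training set; no stain normalization
is applied anywhere.

## Training harness

The harness implements the transfer-learning contract: a backbone of
ordered stages, the first `frozen_depth` (default 3) of which never update,
with a fresh 2-class head; cross-entropy; batch size 128; 18 epochs; weight
decay 1e-4; cosine annealing lr(t) = min + (max−min)(1+cos(πt/T))/2 from
max 2e-2 (min_lr unstated, default 0); optimizer unstated, default SGD with
momentum 0.9 to match the schedule style. "First three convolutional
layers" is read as the first three backbone stages. Freezing is verified by
SHA-256 checksums over raw parameter bytes before/after training.

The bundled backbone, `tiny-cnn`, is four strided 3×3 conv stages
(3→8→16→32→32, stride 2) with global average pooling and a linear head,
implemented in numpy with explicit forward/backward passes. Freezing the
first three stages mirrors the stage-freezing protocol structurally while
training in seconds on one CPU; with those stages frozen at their seeded
initialization they act as a fixed random feature extractor, which
preserves the color information the synthetic task carries. The harness is
backbone-agnostic: any staged network implementing the same interface plugs
into the freezing, schedule and optimizer machinery unchanged. Training is
deterministic given the seed under a fixed thread policy (single-threaded
numpy; initialization and data order are seeded).

Capability is calibrated on a dedicated **separable fixture**: a
calibration slide whose 90 px cells are rendered wholly tumor or wholly
normal, making the patch classes linearly separable in mean color. The full
18-epoch protocol reaches ≥ 0.95 held-out accuracy on it in a few seconds.
Realistic slides with mixed-content boundary patches are harder and are
evaluated in the grid and shift experiments without that bar.

## Whole-slide inference and metrics

The sliding window visits consecutive non-overlapping 90 px tiles; entry
(r, c) of the probability matrix is the classifier's positive probability
for the tile anchored at (c·90, r·90). The output is invariant to batch
size and visiting order. Classification applies the 0.5 threshold with ties
resolved **negative** (configurable). The ground-truth grid rule at test
time is unstated in the source protocol; we use θ_gt = θ_pos = 0.20 for
train/test consistency and assign intermediate-content cells negative so
the grid is exhaustive (both exposed in config). Partial edge tiles are
excluded, consistent with tiling.

Metrics follow the printed formulas: ACC = (TP+TN)/total, SEN = TP/(TP+FN),
SPE = TN/(TN+FP), precision = TP/(TP+FP), F1 = 2TP/(2TP+FP+FN). The
weighted F1 is the support-weighted mean of the per-class F1s (the negative
class's F1 treats negatives as the class of interest); both variants are
always emitted. Zero-denominator metrics are reported as 0 with an explicit
degenerate flag, never as silent NaN — on a slide whose grid has no positive
cell, sensitivity is degenerate and the weighted F1 is dominated by the
negative class, which is why near-empty slides score high F1 even at zero
sensitivity. AUC-ROC uses tie-aware trapezoidal integration over
patch-level probabilities pooled per slide. Aggregation tables report mean
and sample SD (n−1; population vs. sample is unstated in the source).

## Synthetic slide generator

The generator emulates the statistical structure of the data regime, not
histology. Geometry: a tissue region from thresholded low-frequency noise
(exact top-k selection so the realized pixel count equals
round(fraction·H·W)); lesions as Gaussian bumps plus a smooth irregularity
field, again realized by exact top-k, so the measured tumor fraction equals
the target at pixel resolution; fibrosis as the next-highest band of the
lesion field, forming a ring around lesions that pushes mixed patches
across the 20% threshold. Lesion centers snap to patch-grid cell centers by
default (configurable) so even the smallest study burden (0.03% of a
2700² slide ≈ 2200 px) concentrates in one grid cell above the 20%
ground-truth rule rather than splitting across four neighbours. Negative
slides keep white background inside the bounding box; background pixels
equal the configured background exactly.

Appearance: per-pixel HSV rendering with per-slide hue/saturation draws,
low-frequency spatial jitter, a global contrast gain around mid-gray, and
Gaussian texture noise. Tumor tissue occupies a hue band disjoint from
normal tissue, so a simple color rule separates the classes — a deliberate
property that makes oracle tests and desk-scale learning possible. Two
built-in styles differ in contrast and saturation: `local`
(muted pink, gain 1.0) and `external` (washed out: gain 0.6, lower
saturations, shifted hues). The magnitude of this gap is a free parameter;
the default is chosen so that a model trained on one source measurably
degrades on the other — the premise the domain-shift experiment probes.
With a milder gap the single-source model generalizes at ceiling and the
comparison is decided by noise. Fibrosis in cohorts scales with tumor
burden (fibrosis = 0.4 × tumor fraction by default), reflecting its
tumor-associated nature.

What the generator does **not** model: nuclei and cellular morphology,
stain deconvolution physics, scanner optics, pyramidal formats, and
poorly differentiated tumor that resembles normal tissue. Passing tests
therefore demonstrate the pipeline's correctness and the direction of the
domain-diversity effect under controlled shift — not clinical performance
on real slides.

## Experiments and problem sizes

Desk-scale defaults (one CPU): training slides 1260² px (14×14 patch grid),
four positive burdens {10, 15, 22, 28}% plus two negatives per domain;
whole-slide testing cohort 2700² px with the five study burdens
{0.03, 0.35, 5.11, 18.64, 29.41}% plus two negatives. The grid experiment
trains one model per (design, augmentation) cell — eight cells — and
evaluates both phases; the shift experiment trains {local-only, mixed
50/50} × {augmentation off, on} across ≥ 3 replicate seeds (refusing fewer
than 2, where the SD is undefined) and scores whole-slide weighted F1 on
unseen external-domain slides. Replicate seeds are an extension over the
single-model-per-cell protocol so that the arm SDs are meaningful; they are
labeled as such in outputs. At these sizes the augmented arms have high
variance (the destructive α draws hit hard when a training set has only a
few hundred patches); the stable, reproducible effect is the mixed-source
arm outperforming the local-only arm under shift, with the single-source
failure expressed mainly as false positives on the washed-out domain.

## Known limitations

* The color-separable synthetic task is far easier than histopathology;
  absolute metric values do not transfer to real slides.
* Union-only polygon semantics on labelme import (no hole subtraction).
* Patch-level splitting reproduces the original leakage-prone protocol by
  design; use the whole-slide phase for honest generalization estimates.
* The numpy backbone is intentionally small; it demonstrates the protocol,
  not state-of-the-art capacity. Heavier staged backbones must be supplied
  by the caller through the same interface.
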