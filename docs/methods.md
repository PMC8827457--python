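# Methods and design notes

This document records the modeling assumptions, parameter choices, and
numerical decisions behind the package, and what they imply about scope.

## Coordinate convention

All modules share one normalized frame over the pregnant abdomen:

* **axial**: 0 = pelvis, 1 = fundus;
* **lateral**: 0 = maternal right, 1 = maternal left;
* **depth**: 0 = anterior (probe side), 1 = posterior.

Sweep geometry lives in a registry (`localization.SweepGeometry`): four
vertical sweeps (frames ordered along the axial axis) at lateral band
centres 0.2/0.4/0.6/0.8 and four horizontal sweeps (frames ordered along
the lateral axis) at the same axial centres, band half-width 0.125. A real
protocol's measured geometry can be substituted via a JSON registry file;
nothing downstream assumes the default stations.

## Phantom generator

The phantom is a noiseless 3D scene evaluated analytically at each frame's
pixel grid — no volume array is stored.

* Abdomen: homogeneous block, default 240 × 200 × 160 mm (axial × lateral
  × depth), intensity 0.35.
* Fetal head: ellipsoid with a bright rim (intensity 0.75 outside 80% of
  the normalized radius) and dark interior (0.12). The default semi-axes
  (50, 42, 42) mm are prolate — the two transverse axes equal — so any
  plane through the centre that contains the long axis shows the maximal
  cross-section. This makes the analytic ground truth recoverable from the
  2D sweeps: true BPD = 2 × second-largest semi-axis, true HC = Ramanujan
  perimeter of the two largest semi-axes.
* Placenta: a 30–40 mm slab on the anterior wall, posterior wall, or
  fundus, intensity 0.6 with a ±0.08 separable sinusoidal texture, head
  region excluded.
* Speckle: unit-mean multiplicative gamma noise (shape 1/σ², scale σ²,
  default variance 0.05), applied after rasterization and clipped to
  [0, 1]. Per-frame generators are seeded from (exam seed, sweep id, frame
  index), so exams are bit-reproducible and frames are independent.
* Frames: rows sample the full depth extent; columns sample a
  field-of-view window (default 0.6 of the orthogonal axis) centred on the
  sweep's band, as a convex-probe fan would. Pixel spacing is carried per
  axis so biometry stays in millimetres after resizing.
* Label convention: "cephalic" phantoms place the head's axial centre in
  the pelvic half (sampled 0.24–0.35), "non-cephalic" in the fundal half
  (0.65–0.76); the sampling ranges keep the whole ellipsoid inside the
  abdomen at the largest sampled semi-axis.

## Segmentation network

No deep-learning framework is used: `nn.py` implements Conv2D (im2col with
`sliding_window_view`, one BLAS GEMM per layer; the input gradient is the
same-padding correlation with the flipped kernel, so backward reuses the
im2col GEMM), BatchNorm2D with running statistics, ReLU, 2×2 max-pooling
with argmax routing, nearest-neighbour upsampling, and Adam. Everything is
float32.

The U-Net follows the classic layout: per level two 3×3 conv + BN + ReLU,
2×2 max-pool, filters doubling; a two-conv bottleneck; per decoder level a
2× upsample followed by a 2×2 up-convolution halving the filters, skip
concatenation, and two 3×3 convs; a final 1×1 sigmoid convolution. At
depth *d* this gives 5·d + 3 convolutional layers — 23 at the default
depth 4 (and 18 at depth 3; note that counting from the layer recipe is
the authoritative definition used by `UNet.conv_layer_count`).

Training: binary cross-entropy with Adam (default 1e-3), batch 16, with
Dice and Jaccard monitored per epoch. The train/validation split holds out
a seeded 20% of the *structure-present* frames; all background frames stay
in the training pool. Default epoch budgets: 20 (head), 40 (placenta).
Class rebalancing randomly deletes background frames toward 1:2
(positives:negatives) for the head and 1:1 for the placenta, never touching
positives; when the dataset is already positive-rich the target is
infeasible and everything is kept with a recorded warning. A dataset with
no positive frame at all trains on everything (the constant-zero target is
learnable) and records a warning rather than failing.

## Likelihood maps

The map is an all-zero matrix sized (longest vertical sweep) × (longest
horizontal sweep). Each sweep's boolean detection series is upscaled to
the matching dimension by nearest-index repetition
(`src = (j·n) // target`; downscaling is rejected), then painted: vertical
sweeps add 1 to the detected rows across the columns of their lateral band
(`floor(lo·n)` to `ceil(hi·n)`), horizontal sweeps add to the detected
columns across their axial band rows. Votes from overlapping sweeps add.
Smoothing is a Gaussian blur with reflective boundary — symmetric kernel +
reflection preserves total mass exactly — with default σ = 0.03 × the
larger map dimension; σ = 0 returns the raw vote matrix.

Detection series come from thresholding mask areas (default ≥ 30 px at
network resolution) and discarding runs of fewer than 3 consecutive
detections: a real structure stays in view across neighbouring frames,
isolated hits are noise.

## Classification rules

All thresholds are plain declared parameters (`ClassifierParams`), not
learned.

* **Presentation**: cephalic iff the head map's mass-weighted axial
  centroid < 0.5; indeterminate when the map is empty.
* **Placental location**, in rule order: *indeterminate* (empty map) →
  *fundal* (axial centroid ≥ 0.75) → *anterior* (depth statistic ≤ 0.45)
  → *posterior* (depth ≥ 0.55) → *fundal* fallback (a straddling placenta
  has ambiguous depth). The depth statistic is the area-weighted mean of
  within-frame mask row centroids over all placenta-detected frames, since
  the axial × lateral map cannot see the anterior/posterior axis.
* **Low placenta flag**: raised when the placenta map's axial centroid
  ≤ 0.10 — a referral signal for possible previa, not a previa diagnosis.

## Biometry

The single largest head mask across all sweeps is measured (ties break to
the lowest sweep id, then frame index). An equivalent ellipse comes from
the second central moments of the filled mask: a uniform filled ellipse
with semi-axis *a* has coordinate variance *a*²/4, so the semi-axes are
2·√(eigenvalues of the coordinate covariance); anisotropic (row, col)
pixel spacing scales coordinates before the fit. BPD is the full minor
axis in mm. HC defaults to the arc length of the marching-squares contour
at the 0.5 level of the Gaussian-smoothed mask (σ = 1.5 px, padded) —
smoothing removes the rasterization staircase and recovers a sub-pixel
boundary; the Ramanujan perimeter of the fitted ellipse is available as an
alternative (`method="ellipse"`). Both are accurate to well under 2% for
semi-axes ≥ 15 px.

Gestational age uses published polynomial regressions on BPD or HC
(weeks on centimetre inputs), shipped as `data/ga_formulas.json` so
formulas are data, not code; out-of-range inputs still return an estimate
but carry a warning, and an `identity_stub` formula supports testing.

Trained models predict at network resolution (128 × 128); the probability
map is bilinearly interpolated back through the recorded crop/resize
transform before thresholding, recovering sub-pixel boundary placement at
native resolution. The ground-truth oracle is evaluated at native
resolution directly.

## Agreement statistics

Written out from their contingency/ANOVA definitions and cross-checked in
the test-suite against independent implementations (scikit-learn κ,
pingouin ICC, SciPy t-tests) to 1e-8:

* percent agreement = 100 · trace / total;
* Cohen's κ = (p₀ − p_e)/(1 − p_e), exactly 1 for any perfect-diagonal
  table, undefined (flagged) when both raters use a single category; the
  per-table p-value is the large-sample z-test of κ = 0 (Fleiss H₀
  variance), and `kappa_ttest` offers the across-folds one-sample t-test;
* interpretation bands at 0.2/0.4/0.6/0.8 (slight … almost perfect);
* ICC(A,1): two-way absolute-agreement single-measurement ICC from the
  ANOVA mean squares;
* Bland–Altman: bias = mean(model − reference), limits ±1.96 SD, paired
  t-test for the bias (p = 1 for identical vectors);
* relative error: per-pair |pred − ref|/ref, then averaged (not the
  difference of means);
* fundal-exclusion analysis: `ConfusionTable.drop_label` removes the
  label's row *and* column, i.e. every case where either rater used it.

## Cross-validation harness

One fold per patient; the test patient's frames are excluded from training
(asserted, and re-checkable via `audit_leakage`). Per-fold training seeds
are `master_seed + fold_index`, so folds are independent but the run is
reproducible. Folds whose training pool has no positive frame are skipped
with a recorded reason. Model selection aggregates ranks over seven
metrics (sensitivity, specificity, PPV, NPV, Jaccard, pixel accuracy
descending; area error ascending) because the metrics live on different
scales; NaNs take the worst rank and ties break to the lowest fold index.
Hold-out evaluation pairs each exam's diagnosis with a reference reading;
references marked `"unable"` (or None) are excluded per endpoint and
counted.

## Problem sizes

The shipped defaults are sized for a single CPU:

* phantom frames ≈ 160 × 120 px at 1 mm spacing, 12–24 frames per sweep;
* network input 128 × 128; the small training configuration (depth 3,
  8 base filters, 10 epochs, ~300 frames) reaches > 0.9 validation Dice in
  a few minutes; the full 23-layer/64-filter configuration is implemented
  and tested for correctness but not sized for routine CPU training;
* LOOCV demonstrations use 3 phantom patients.

## Limitations

* The phantom is a geometric stand-in: no acoustic shadowing, no fan
  geometry distortion, no fetal body, no twins. Claims verified on it are
  claims about the pipeline's correctness, not about clinical accuracy.
* The anterior/posterior decision relies on the within-frame depth
  centroid of placenta masks; a heavily wrapped lateral placenta could be
  ambiguous, which the fundal fallback absorbs.
* Presentation is a head-position proxy (pelvic-half vs fundal-half mass);
  it does not distinguish breech subtypes or transverse lie.
* Gestational-age regressions are third-trimester population formulas;
  the package reports their output and validity-range warnings without
  clinical interpretation.
* The NumPy network trains small configurations only; there is no GPU
  path, no data-parallelism, and no early stopping beyond the divergence
  guard.
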