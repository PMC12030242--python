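# Methods

This note documents the models, defaults and numerical conventions behind
`texlai`, and what the synthetic experiments do and do not establish.

## Synthetic experiment generator

### Treatment model for LAI

The latent true LAI of a plot is additive:

    LAI = base + mulch(m) + nitrogen(N) + ε_season + ε_plot,   LAI ← max(LAI, 0.05)

- `base_lai = 0.9` (dimensionless, as all LAI here, cm² cm⁻²).
- Mulch offsets: no mulch 0, straw +0.35, plastic film +0.7 — film mulching
  warms and conserves soil moisture, so it ranks highest.
- Nitrogen response: saturating `max_gain · (1 − e^(−N/half_sat))` with
  `max_gain = 1.51712`, `half_sat = 90 kg·hm⁻²`, and a linear decline of
  0.15 per 70 kg beyond the optimum 210 kg·hm⁻² (luxury-N decline).
- Noise: season effect sd 0.15 and plot effect sd 0.2, drawn independently
  per sample; floor at 0.05 keeps relative errors finite.

The calibration makes the film-mulch + 210 kg N cell the expected maximum
with E[LAI] = 2.97 and puts the realized 90-plot range at roughly 0.5–3.5,
typical of oilseed rape at bolting. The two noise terms are the only
emulation of measurement/field variability; there is no real within-season
correlation structure.

### Radiative model for scenes

Canopy mean reflectance per band follows a Beer–Lambert-style saturating
curve

    μ_b(LAI) = soil_b + (leaf_b − soil_b) · (1 − e^(−k_b · LAI))

with soil reflectance (0.10, 0.14, 0.18, 0.20, 0.22, 0.25) and canopy
asymptotes (0.04, 0.10, 0.04, 0.25, 0.40, 0.50) for B/G/R/RE1/RE2/NIR —
red and blue decrease with LAI, red edge and NIR increase — and `k_b = 1.0`
for every band. With k = 1 the curves flatten above LAI ≈ 2.5, which
reproduces the practically important saturation of ratio vegetation indices
in closed canopies.

Each scene additionally receives:

- a per-band multiplicative brightness jitter, sd 0.05, drawn once per
  scene — a stand-in for illumination, view-geometry and leaf-biochemistry
  variability that real reflectance carries but LAI does not explain. This
  term matters: without it the plot-mean reflectance is a noiseless
  bijection of LAI and any monotone regressor inverts it perfectly, leaving
  texture fusion nothing to improve on;
- pixel-level texture: a stationary Gaussian field (white noise smoothed
  with a σ = 2 px kernel, re-standardized) scaled by
  `(0.10 + 0.10·LAI/3.5) · |leaf_b − soil_b|`, so local variability grows
  with LAI and contrast-type GLCM features carry signal;
- canopy gaps: cover fraction `1 − e^(−0.9·LAI)` imposed by thresholding a
  second correlated field, so sparse canopies are gappier — a second,
  geometric route by which texture tracks LAI;
- soil pixels at soil reflectance with sd 0.005 noise; everything clipped
  to [0, 1], stored float32.

Plots are rendered at 48×48 px (≈ 2 m of row at centimeter ground sampling
distance); the size keeps a full 90-plot texture extraction in a few
seconds while leaving ~1 700 full 7×7 windows per plot.

What passing tests on this generator show: the pipeline recovers a known
signal end-to-end, orderings (three-term > two-term indices, fusion ≥ VIs
alone) emerge for the stated structural reasons, and every numerical
component matches independent oracles. What they do not show: performance
on real canopies, where soil/shadow segmentation errors, registration
noise, non-Gaussian texture and between-field variation all matter.

## Texture features

- Quantization: per band, linear min–max scaling to `G = 32` levels over
  the vegetation-masked pixels (values outside clip to the end bins);
  a constant band maps to level 0. G = 32 balances gray-level resolution
  against the 36 pairs available in a 7×7 window at offset (1, 1).
- Co-occurrence: offset (dx, dy) = (1, 1) pairs pixel (r, c) with
  (r+1, c+1); symmetric accumulation (transposed pairs added) is standard
  practice and stabilizes COR on tiny windows.
- Window placement: only windows fully inside the raster, centered on a
  masked pixel; the plot value is the unweighted mean over those windows.
- Conventions: ENT is implemented as −Σ P log P ≥ 0 (natural log); COR uses
  the standard √(VAR_i·VAR_j) denominator and is defined as 0 when either
  marginal variance vanishes, keeping COR ∈ [−1, 1].
- The sliding-window implementation counts pairs sparsely (sorted pair-id
  run-length encoding) and is verified against an explicit loop oracle to
  1e−10 on random images.

## Vegetation indices

Computed from plot-mean band reflectance (mean first, index second — the
alternative per-pixel-index-then-mean is available in `predict_map`'s
windowed features). TVI is implemented with the radical, √(NDVI + 0.5);
GNDVI as (NIR−G)/(NIR+G); CVI as (2·NIR−R−G)/(2·NIR+R+G). An index with a
vanishing denominator returns NaN for that record rather than raising.

## Index search

- Ordered tuples with repetition: asymmetric formulas make order matter,
  and repeated labels are legal (a reciprocal family can use the same
  feature twice).
- Maximize |r|, report signed r: families can be anti-correlated with LAI;
  the search is direction-agnostic.
- Validity: a tuple needs finite index values for ≥ 80 % of samples and a
  nonconstant index column; reciprocal families explode near zero-valued
  features (COR ≈ 0 especially), and excluding rather than imputing keeps
  the correlation honest.
- Ties break to the lexicographically first label tuple (columns sorted,
  first arg-max), making results reproducible.
- p-values use t = r√((n−2)/(1−r²)) on n−2 df, two-sided. No multiplicity
  adjustment is applied anywhere — the screening applies a raw p < 0.05 per
  variable, and the search reports the maximum of ~10⁵ correlations. The
  reported p of a searched optimum is therefore optimistically biased; this
  is a faithful property of the emulated procedure and a known limitation.

## Estimation grid

- Split: uniform random 2/3 modeling (floor), 1/3 validation; one split
  shared by all 45 cells; seeded.
- SVM: poly kernel, C = 20, γ = 0.02, degree 3 (degree is an exposed
  default; the poly degree is otherwise unspecified). Features standardized
  by a scaler fitted on the modeling set only.
- PLSR: latent-variable count by a sequential gain rule — starting from one
  LV, add LV k+1 only while 5-fold cross-validated explained Y-variance
  (100·CV-R², shuffled folds, fixed seed) gains ≥ 5 percentage points;
  capped at min(10, #features, n−2). Train-only standardization, PLS's own
  scaling disabled. Note the collinearity-invariance of PLS predictions
  (duplicate columns changing nothing) holds exactly when the LV count
  reaches the predictor rank, not at truncated counts.
- XGBoost: 100 estimators, learning rate 0.03, max depth 5, single thread,
  fixed `random_state`; trees need no standardization.
- Metrics: R² = 1 − SSres/SStot (not squared Pearson — it penalizes bias),
  RMSE in LAI units, MRE = 100·mean(|y−ŷ|/y) %. R² is flagged NaN for a
  zero-variance truth vector.
- Block resolution: VIs and TFs are the p < 0.05 screened columns; TIs/TTIs
  are the 6 + 5 best-tuple index columns materialized per sample. Rare NaN
  entries in an index column (samples outside its finite support) are
  filled with the column median so fits see complete data.
- Inversion maps: per-pixel features come from each masked pixel's own 7×7
  window (window-mean reflectance for VIs, window GLCM for TFs, best tuples
  for TIs/TTIs); border pixels without a full window are no-data, and
  predictions are clamped at 0 since LAI is non-negative. Per-window
  features are noisier than plot means, so linear models can extrapolate at
  extreme windows; the clamp bounds only the physical impossibility.

## Degenerate inputs and errors

Empty masks, windows with no valid pixel pair, zero-variance correlation
inputs, all-invalid search spaces and sub-3-sample splits raise typed
errors (`texlai.errors`); division by zero inside index formulas returns
NaN markers instead. A constant training target yields a constant
predictor with R² flagged undefined.

## Problem sizes

Default experiments use 90 plots of 48×48 px; the exhaustive search
evaluates 6·48² + 5·48³ ≈ 5.7×10⁵ correlations vectorized over samples; the
multi-seed ordering properties use 20 generator seeds. A full pipeline run
completes in seconds on one CPU.
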