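# Methods

This note documents the models, conventions and numerical choices
behind `echotex`, and what the synthetic benchmarks do and do not show.

## Texture model

**Co-occurrence counting.** For a gray image quantized to G levels
(default G = 256, the native 8-bit scale), the co-occurrence matrix for
displacement (Δr, Δc) counts *ordered* pixel pairs (p, p + d); pairs
whose displaced pixel leaves the ROI are skipped, so for a 50×50 ROI
and displacement [0 1] there are exactly 50·49 = 2450 pairs.
A `symmetric` option adds transposed pairs, but the default is the
directional (asymmetric) form: since features are averaged over the
four displacements [0 1], [−1 1], [−1 0], [−1 −1] (the 0°/45°/90°/135°
distance-1 set), orientation dependence is already suppressed.

**Features.** With p(i, j) = counts/n_pairs:
ASM = Σp², entropy = −Σ p ln p (0·log 0 ≡ 0; natural log by default,
base selectable), IDM = Σ p/(1+(i−j)²), contrast = Σ (i−j)² p, and
correlation = cov(i, j) normalized either by σxσy (`haralick`, the
Pearson form bounded by ±1) or by σx²σy² (`walker`, default). The
variance-product form is the package's reading of the plugin-style
correlation used in the muscle-ultrasound literature it models; it
produces magnitudes of order 10⁻³ on speckle ROIs, consistent with the
reported cohort means for that workflow, whereas the Pearson form is
order 1. Both are exposed and recorded in output provenance; for a
constant ROI the marginal variances vanish and correlation is reported
as an explicit NaN marker, never silently as 0.

**Averaging modes.** Default is feature-level averaging (compute the
five features per displacement, arithmetic-mean them); matrix-level
averaging (mean the four probability matrices, then compute features
once) is available because "averaged four-direction value" is genuinely
ambiguous in this literature. The two agree on isotropic degenerate
inputs and differ in general; the mode is recorded in provenance.

**Offset invariance, exactly.** The motivating robustness claim is that
second-order features ignore a constant brightness shift. The
implementation makes this *bit-exact*, not approximate: features are
computed from the sparse nonzero triplets of the count matrix, which a
global gray shift translates without reordering, and the correlation
feature re-centers row/column indices at their minimum occupied level
(covariance and variances are invariant to per-variable offsets). The
test suite asserts exact equality under shift for both correlation
variants, and that EI moves by exactly the shift.

**Quantization.** `levels = L` rebins by equal-width intervals,
bin = ⌊gray·L/256⌋. Native 256 levels is the default throughout; small
L exists for oracle tests and robustness studies. Note this means small
test images must place their gray values on the 0–255 scale.

## Image generator

The ROI generator emulates only what second-order statistics see:

* **Speckle**: the Rayleigh-like envelope √(g₁²+g₂²) of two independent
  Gaussian fields smoothed with a Gaussian kernel of width
  `speckle_scale` (default 1.5 px — speckle grain a few pixels across),
  scaled to relative contrast `speckle_amplitude` (default 0.35) around
  `base_level` (default 60, matching a typical muscle EI of ~60 AU).
* **Infiltration**: `round(n_streaks·h)` bright elongated Gaussian
  streaks (random position/orientation, length 0.3–0.8 of the ROI,
  width 1–3 px) with peak brightness `infiltration_brightness·(0.3+0.7h)`
  where h ∈ [0,1] is the heterogeneity parameter. Fat and fibrosis are
  hyperechoic, so infiltration raises EI and entropy together — the
  positive EI–entropy association seen in real muscle falls out of the
  rendering rather than being imposed.

Heterogeneity is unitless by construction: there is no quantitative
composition ground truth (fat %, fibrosis %) to calibrate it against.
The generator is deterministic per (config, seed), bit-exactly.

**Not modeled**: beam physics, attenuation, time-gain compensation,
anatomy (bone shadow, fascia), depth dependence. Passing texture tests
on these images therefore demonstrates correctness of the *feature
machinery and its monotone response to infiltration-like structure*,
not performance on clinical images.

## Cohort generator

Each subject carries a latent quality q ~ N(0,1). The rendered ROI uses
heterogeneity Φ(−q) (worse quality → more infiltration), and texture
features are *measured from the rendered pixels*, so feature noise has
the same origin as in a real analysis — finite-ROI sampling. Function
tests are s = w·q + √(1−w²)·ε mapped affinely to the published cohort
means/SDs (age 64.6 (10.9) y, ISWT 433.0 (178.7) m, …) and floored at
zero; the mixing weight w is solved numerically (bracketed root find)
so the realized Spearman correlation between the anchor feature
(entropy by default) and each test equals the requested target. Because
the anchor is measured before the solve, the calibration is exact up to
rank granularity; the zero floor affects <1% of subjects at the default
settings and shifts realized ρ by ≪0.01. Targets are anchored on one
feature: the other features' correlations follow from their coupling to
the anchor through q, mirroring the strong mutual correlation of GLCM
features in real cohorts. Demographics and labs are drawn independently
of q from the published summary distributions.

Missingness: MCAR masks eligible cells (labs + function tests)
uniformly at the requested rate; MAR uses a logistic model on observed
age (slope 1.5 per SD, intercept solved to hit the marginal rate), so
older subjects are more likely to miss assessments. Age itself is never
masked, keeping the MAR mechanism conditionally ignorable given
observed data.

## Statistical layer

* **Spearman**: average ranks for ties, Pearson on ranks, two-sided p
  from the t approximation on n−2 df (adequate in the n≈90 regime); a
  pairing-permutation option exists for very small n. Pairwise deletion
  per cell; cells with <3 pairs or zero rank variance are explicit
  undefined markers excluded from aggregation.
* **Fisher-z averaging**: z′ = artanh r per coefficient, arithmetic
  mean, back-transform tanh. Report rounding is 3 decimals,
  round-half-even. |r| = 1 inputs are outside the transform's domain; a
  degenerate grid cell is capped at 0.999999 with a warning rather than
  aborting the whole table.
* **EM imputation**: multivariate-normal working model; E-step fills
  conditional means and accumulates conditional covariances per
  missingness pattern, M-step updates moments; convergence when the
  observed-data log-likelihood changes by < tol (default 1e−6, max 200
  iterations). The final fill is the conditional mean — deterministic,
  no residual draw — with a seeded stochastic-draw option for
  sensitivity analyses. On complete data one M-step reproduces the ML
  sample moments exactly. Non-PD covariance iterates are repaired by a
  minimal ridge, logged; singular observed blocks fall back to a
  pseudo-inverse with a warning.
* **Little's MCAR test**: d² = Σ_patterns n_j(ȳ_j−μ̂_obs)ᵀΣ̂_obs⁻¹(ȳ_j−μ̂_obs)
  with EM-ML moments, df = Σ_j p_j − p, chi-square reference.
  Calibration is verified by simulation (p-values uniform under MCAR;
  power > 0.5 against a strong MAR mechanism).
* **Standardized GLM**: outcome and predictors z-scored, OLS with
  intercept; β are fully standardized, t on n−k−1 df. Sex coded
  female=0/male=1; ethnicity collapsed to a White/non-White indicator
  (the modeled analysis reports a single ethnicity coefficient).
  Rank-deficient designs fail loudly, naming the collinear columns via
  pivoted QR. Covariates entering the GLM are EM-imputed; correlations
  never use imputed values — imputation and pairwise deletion serve
  different tables, deliberately.
* **Variance explained**: joint OLS R² of an outcome on the five
  features. GLCM features are strongly collinear, so the condition
  number is logged and exactly aliased columns are dropped with a
  warning; joint R² is one defensible reading of "% variance explained"
  for a collinear feature set, and is flagged as such.
* **ICC**: ICC(2,1), two-way random effects, absolute agreement, single
  measurement — a convention choice, since reliability reports in this
  literature rarely state the form. The consistency form ICC(3,1) is
  reported alongside (a constant shift between passes lowers absolute
  agreement but not consistency), plus the paired-t difference p. Zero
  between-subject variance yields an explicit undefined marker.
* **Multiple testing**: none by default, matching the modeled workflow
  (α = 0.05); a Benjamini–Hochberg toggle is available on the
  correlation grid consumer side but off by default.

## Reference grid

`echotex.reference` packages the published feature-by-test Spearman
grid and its Fisher-z average column (ASM 0.130, entropy −0.177,
IDM 0.167, correlation 0.150, contrast −0.147) for a 90-patient CKD
cohort. The aggregation of that grid is the one desk-checkable output
of the whole analysis and is asserted to 3 decimals; the underlying
per-patient values are not available, so individual cells, cohort
means, GLM betas and ICC values from that report are *not* treated as
reproduction targets anywhere in the package. Two of the published
cohort summary values (mean entropy 25.1, IDM 0.36 (0.78)) are
mathematically inconsistent with the normalized feature definitions
used here (entropy of a 2450-pair matrix is bounded by ln 2450 ≈ 7.80;
IDM ∈ (0,1]), which points to a different scaling in the original
plugin; the package documents its normalized definitions and makes no
attempt to match those two numbers.

## Problem sizes in the validation suite

Oracle equivalence runs >100 random images up to 12×12 with ≤8 occupied
gray levels against a literal double-loop implementation (tolerance
1e−10). Texture monotonicity uses 30 seeds per heterogeneity level on a
5-level grid with trend tests at α = 0.01. Cohort calibration is checked
at n = 5000 (±0.03 band at targets ±0.25); EM moment recovery at
n = 2000 with 10% MCAR (3-SE band); Little's-test calibration over 150
MCAR replications of n = 250 (KS at α = 0.01). These sizes give stable
Monte-Carlo verdicts while keeping the full suite under a minute.

## Known limitations

* The image model is statistical, not physical; absolute feature values
  do not transfer to clinical scanners.
* Cohort calibration is exact only for the anchor feature; other
  features' effect sizes are emergent, not controlled.
* The EM working model is Gaussian; heavily skewed labs violate it
  (as they do in the workflow being modeled).
* The walker correlation normalization is a documented interpretation
  of an under-specified plugin formula, not an established standard.
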