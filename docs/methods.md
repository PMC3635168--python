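# Methods

## Scope and model

`hgfish` analyses single-season fish surveys in which each fish carries a
total length (mm TL), wet-weight tissue mercury (ppm), and optionally δ15N
(‰), otolith age (years) and sex. All mercury values are ppm wet weight
(mg/kg fresh tissue); dry-weight laboratory values are converted at ingest
by `hg_ww = hg_dry × (1 − %moisture/100)`. Hg is log10-transformed before
every regression, correlation and group comparison (lognormal residuals;
normality and variance homogeneity on the log scale).

### Trophic position

`TP = (δ15N_fish − δ15N_baseline)/3.4 + 2`, with 3.4‰ the per-trophic-
transfer nitrogen fractionation and the baseline set by the lake's benthic
invertebrate composite, assumed to sit uniformly at trophic level 2. The
baseline δ15N of a lake is the mean of its composite measurements. Negative
TP values are allowed (they signal a baseline mismatch) and logged.
Limitation: mixed-guild invertebrate composites (partially predacious taxa)
bias TP low; no correction is applied.

### Hg–length fits and inverse prediction

Within each lake × species cell with ≥3 complete records, OLS of
`log10(Hg) = a + b·TL`. The reported p-value is the model F-test, which in
simple regression equals the slope t-test. Cells whose p exceeds the
significance gate (default 0.05, configurable) are never inverted unless
the caller passes an explicit override; this mirrors standard screening
practice, where non-significant relations give no defensible length
threshold.

Inverse prediction solves `a + b·L* = log10(C)`:

- `b ≤ 0`: the level is never reached; a not-reached estimate is returned.
- `L* < 0`: truncated to 0 mm and flagged (the fitted line already exceeds
  the level at all lengths).
- `L*` outside the observed length range (either side): flagged as an
  extrapolation, rendered with a trailing `*`.
- `L*` above the species' maximum achievable length: flagged and rendered
  `>cap`; this takes precedence over the extrapolation mark in rendering
  (an estimate beyond what the species can grow to is reported as "never
  reached in practice" rather than as a numeric extrapolation).

Thresholds are reported to 0.1 mm. Default caps: bluegill 300 mm, black
crappie 500 mm, largemouth bass 700 mm; the bass cap is a configurable
convention — no published maximum exists for the survey region — and only
affects rendering, never the numeric estimate.

### Biomagnification

Per lake, OLS of log10 Hg on TP using largemouth bass and bluegill
combined; black crappie are excluded because partial collections would make
among-lake comparison inconsistent. The slope is the biomagnification rate
(`10^slope` = concentration multiplier per trophic level; the log10 scale
is forced by the correspondence of slopes 0.61–1.0 with 4–10× factors);
the intercept, back-transformed, is a *relative* index of Hg at the base of
the food web — comparable across lakes, not an absolute water-chemistry
measurement. Slope homogeneity across lakes is tested by ANCOVA: a nested
F-test of `log10 Hg ~ TP + lake + TP:lake` against the no-interaction
model, with treatment-coded lake factors. The test is calibrated: under
equal slopes its type-I error at α = 0.05 is nominal (checked by
simulation in the test suite).

### Correlations

Pairwise correlations are Pearson product-moment with two-sided t-based p
(n−2 df). Partial correlations use the residual method: both variables are
regressed (OLS with intercept) on the controls and the residuals
correlated; p is two-sided t-based with n−k−2 df for k controls. The
residual method is algebraically identical to the inverse-correlation-
matrix formula, which the tests verify to 1e-10, alongside a cross-check
against `pingouin.partial_corr`. Within each lake × species cell the
family is the six reported correlations (3 pairwise + 3 partial), so the
Bonferroni-adjusted per-test threshold is 0.05/6 ≈ 0.008. Complete-case
analysis throughout; no imputation. Cells with a constant factor or
residual collinearity drop that factor's row (logged), never the whole
table.

### Harvest risk

A fish is *harvestable* when TL ≥ the species' minimum length limit
(355 mm bass, 203 mm crappie, none for bluegill). The exceedance
percentage uses strict inequality (`Hg > level`): screening levels are
thresholds *for concern*, so a boundary fish does not count as exceeding.
Species without a limit treat all fish as harvestable; with zero
harvestable fish the percentage is undefined (reported absent, count 0).
`threshold_vs_limit` compares the inverse-predicted screening length with
the limit: `threshold_below_limit` is the management red flag — every legal
fish is predicted above the level.

The routine-monitoring predictor takes, per lake, the arithmetic mean of
untransformed wet-weight Hg over bass in the closed window [320, 385] mm
(the typical agency monitoring size range) and regresses the lake's
inverse-predicted screening-level length on that mean (threshold-on-mean,
not the inverse). Its slope is negative whenever contamination shifts
thresholds down. Both the signed correlation r and r² are reported
(summaries of such regressions sometimes print signed "R²" values; those
are correlation coefficients, and this package keeps the two distinct).

## Synthetic cohort generator

The generator emulates the survey's statistical structure, not mercury
mechanism (no bioenergetics, no elimination kinetics):

1. integer age uniform on [1, 8] years (default; brackets typical
   bluegill/bass mean ages of ~3/~5 years),
2. length = von Bertalanffy mean `L∞(1 − e^{−k·age})` + Gaussian noise
   (resampled positive, rounded to the nearest mm as in the field),
3. expected TP linear in length from `tp_at_min_length` (length 0) to
   `tp_at_max_length` (length L∞) — an ontogenetic diet-shift proxy —
   plus optional Gaussian scatter `tp_noise_sd` (individual diet variation
   and isotope analytical error),
4. δ15N = baseline + 3.4·(TP − 2), the exact inverse of the TP equation,
   so the trophic module recovers the generator's realized TP to machine
   precision,
5. log10 Hg = baseline_log10_hg + slope·TP + Gaussian(0, residual_sd);
   tissue Hg is therefore lognormal and strictly positive.

`generate_study` rejection-samples fish into the stratified 5/5/5
small/medium/large length classes per lake × species (class bounds
115/150 mm bluegill, 203/279 crappie, 355/432 bass) with a bounded attempt
budget; an unreachable class raises, naming the lake/species/class.
Species can be omitted per lake; the default pack omits black crappie from
two of six lakes, emulating partial collections.

Default pack: six lakes spanning food-web baselines 3×10⁻⁵ → 1.8×10⁻³ ppm
(log10 −4.52 → −2.74) and biomagnification slopes 1.00 → 0.61, paired so
the cleanest baselines carry the steepest slopes (the contrast the field
data show). Species trophic ordering bass (3.3–4.2) > crappie (3.0–3.8) >
bluegill (2.6–3.2). Growth: L∞/k of 250/0.35 (bluegill), 400/0.30
(crappie), 580/0.25 (bass), length noise 15/20/25 mm.

Noise calibration: `residual_sd = 0.1` (log10 ppm) with `tp_noise_sd =
0.05` trophic levels in the default pack. The TP scatter is deliberately
non-zero there: with `tp_noise_sd = 0`, TP is an exact linear function of
length and the partial-correlation analysis is degenerate by construction
(residuals of length on TP vanish). The two noise levels were chosen
together so that per-cell Hg–length R² at the design's n = 15 falls in the
0.54–0.92 band typical of field surveys of this kind. With all noise set
to zero the generator is exactly linear: log10 Hg is a deterministic
affine function of TL and downstream fits recover the generative
coefficients to machine precision — the basis of several exactness tests.

What passing synthetic tests does *not* show: the generator has linear
diet shifts, Gaussian noise, no age–Hg path independent of TP, no
system-level covariates (pH, wetland cover), and no measurement error in
length or Hg. Real surveys violate all of these to some degree; the tests
demonstrate internal statistical correctness, not field validity.

## Numerical and design choices

- All OLS fits go through statsmodels; hypothesis tests through
  scipy.stats. Singular designs (constant predictor) raise a dedicated
  error rather than returning NaN fits.
- Delimited tables are written with `%.17g` floats and re-parsed with
  Python's exact `float()`, making write→read an exact identity on
  float64 — the round-trip property the io tests assert.
- Screening-level order USEPA < NC < USFDA implies monotone threshold
  lengths for positive slopes; this is asserted as an invariant.
- The published reference table embedded in `hgfish.datasets` stores the
  printed coefficient values and printed significance text; rebuilt fit
  objects carry no standard errors (not published). One row is printed at
  exactly p = 0.05 with thresholds; grid reconstruction inverts it via the
  explicit override, keeping the strict p < 0.05 gate for fresh fits.
- Stochastic tests are seeded; calibration checks (CI coverage, type-I
  error) use replicate counts large enough that their tolerance bands are
  ≥3 Monte-Carlo standard errors wide.

## Problem sizes

The default synthetic study is 6 lakes × (2–3 species) × 15 fish = 240
fish, matching the stratified design it emulates. Calibration suites use
500 replicate lakes of 60 fish for slope recovery/coverage and 1000
two-lake null replicates for the ANCOVA type-I check; these are the sizes
at which binomial tolerance bands of a few percentage points are
statistically meaningful, and the whole suite completes in seconds.

## Known limitations

- Trophic positioning assumes a single, uniformly level-2 baseline per
  lake and the canonical 3.4‰ fractionation; both vary in nature.
- The biomagnification intercept is a relative index; comparing it across
  studies with different baselines is not meaningful.
- Inverse predictions carry no confidence intervals (calibration intervals
  for x-at-given-y would require the full covariance of (a, b), which the
  published reference table does not provide); extrapolation flags are the
  honesty mechanism instead.
- The monitoring predictor is fitted across lakes of one survey; applying
  it to new regions requires refitting.
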