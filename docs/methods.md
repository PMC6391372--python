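# Methods

This note documents the models, algorithmic choices, and the synthetic
study design behind `sowshift`, including what the passing test suite does
and does not demonstrate about real trial data.

## Feature engineering

Daily weather is aggregated into half-open 30-day windows relative to each
trial's sowing day-of-year: `Wpre` = offsets [−30, 0), `W1` … `W5` =
[0, 30) … [120, 150), plus `season` = [−30, 150). The sowing day itself
belongs to `W1`; offset −1 is the last pre-sowing day. Leap days are
dropped on read so every year has 365 slots and window arithmetic is
uniform; gaps in coverage are an error, never imputed.

Per window the pipeline computes cumulative precipitation and solar
radiation, and means of daily Vpd, Tmax and relative humidity. Vapor
pressure deficit uses the Magnus-type saturation curve
`es(T) = 0.6107·exp(17.269·T/(237.3+T))` kPa evaluated at the daily
extremes, `Vpd = es(Tmax) − es(Tmin)` — an operational proxy for
atmospheric demand that needs no humidity measurement. Relative humidity
divides the observed vapor pressure by the mean of the two saturation
values; values above 1 are permitted but logged (gridded vapor pressure
occasionally exceeds the derived saturation mean). Wet days (`a`,
precip > 1 mm), dry days (`b`, precip < 1 mm) and `a/b` are computed per
window and for the season; days with exactly 1 mm fall in neither count,
and when `b = 0` the ratio is reported as `a/(b+1)` with a companion flag
column, avoiding infinities while preserving ordering.

The interpretation (tree) stage uses exactly 31 predictors: the 5 main
variables × 6 windows, plus the categorical state. Tmin and day length
are computed and stored but excluded from both model stages because they
confound with the retained variables. The prediction (boosting) stage
adds the wet/dry-day features, season-wide analogues, latitude, longitude
and calendar year (the year term absorbs the technology trend; omitting
it would bias the weather coefficients).

## Conditional-inference tree

Variable selection and stopping are statistical: at each node every
predictor is tested against yield with a Monte-Carlo permutation test
(shared permutations across predictors; default 9,999 draws). Numeric
predictors use the absolute centered cross-product statistic, the state
factor a between-group quadratic form. P-values are Bonferroni-multiplied
by the number of predictors; if the minimum adjusted p exceeds α = 0.05
the node becomes a leaf. When several Monte-Carlo p-values saturate at
the resolution floor, ties break by the permutation-standardized
statistic, then column order. The split point maximizes the standardized
two-sample mean contrast over all admissible cuts (≥ `min_terminal`
observations per side, cuts only between distinct values; thresholds
reported at midpoints of adjacent observed values). State splits order
categories by mean yield and cut along that ordering, which is exact for
least-squares criteria and avoids the 2^k subset search.

Defaults target an analysis of a few hundred observations: splits need
> 37 observations, leaves > 18, depth ≤ 10. The asymptotic quadratic-form
test of the reference framework is a valid alternative to the Monte-Carlo
test; the Monte-Carlo route was chosen because it is assumption-free and
its calibration is directly testable (the suite verifies a 5% type-I
error within ±2 points over 1,000 null simulations).

Within-stratum slope regressions (`node_vpd_slope`) are plain OLS of
yield on one window feature, with a state × feature interaction F-test
for slope homogeneity. The pipeline's headline 61–90 DAS Vpd slope is
estimated in the stratum with benign pre-sowing conditions
(`vpd_mean_Wpre ≤ 1.79 kPa`) so the pre-sowing penalty cannot confound
it; the pre-sowing slope is estimated in the complementary harsh stratum.
The naive full-sample slope is reported alongside — in the synthetic
study it is visibly steeper (≈ −1.6 k vs the planted −1,135 kg/ha/kPa),
a deliberate demonstration of why stratification matters.

## Boosting model

Functional gradient descent under squared-error loss: starting from the
training-mean offset, each iteration fits one simple base learner per
feature to the residuals and keeps the best, scaled by the step length
ν = 0.2, for 600 iterations (no early stopping or internal tuning). The
training MSE is non-increasing by construction for ν ≤ 1.

The default base learner is the componentwise simple linear fit, whose
boosting limit is the least-squares solution — the suite verifies
agreement within 1% after the default 600 × 0.2 schedule. Regression
stumps are provided as an alternative but are *not* the default: stumps
are piecewise-constant, so predictions saturate at the edge of the
training feature range, and the counterfactual scenarios deliberately
push window features beyond that range. In design-stage dry runs stump
extrapolation flattened the late-sowing side of every response curve and
biased all recovered optima roughly ten days early; linear base learners
extrapolate the fitted per-kPa responses and recover the planted curves.

The train/test split is stratified by states within years: within each
year, `round(n·0.85)` of that year's state records train the model (never
fewer than one per side for strata of ≥ 2; singletons go to train, with a
log message). Evaluation reports squared-Pearson R² and RMSE on the
held-out rows.

## Counterfactual scenarios and response optima

Scenario features are ordinary window features with the anchor moved:
weather is never resampled. The anchor is the state's typical sowing date
(decade-mean of its trials, rounded), so the −30…+30 grid is identical
across the ten years of a state; features are built per trial location
and averaged across the state-year's locations before prediction. Failed
feature builds (coverage gaps) are collected as row-level errors and the
run continues.

Per state, the simulated yields are fitted with
`yield ~ shift + shift² + C(year)`; the year intercepts absorb both the
technology trend and each year's overall weather level, a two-stage
reading of the hierarchical model in which year is a grouping level and
the quadratic shift response is the fixed effect of interest. (A full
REML mixed model is a valid alternative; recovery, not the fitting
engine, is the acceptance standard, and with a balanced 7 × 10 grid the
two coincide for the fixed part.) The optimum is the vertex −b/(2c) of a
concave fit, clipped to [−30, +30] and flagged when clipped; convex fits
fall back to the best grid endpoint, flagged. The gain is the fitted
yield at the optimum minus at zero, non-negative by construction for
concave fits. The between-year intercept variance is reported as the
year-level variance component.

The national summary excludes states with positive (later-than-typical)
optima by default — configurable — and production-weights both the mean
optimal shift and the total percentage yield change; an unweighted option
exists because the weighting convention of such headline numbers is
rarely stated.

## Economics and frost screening

Monetary effects follow three steps per state: the percentage yield
change at the optimum is applied to each year's production; each year's
total soybean income is deflated to 2016 US$ via a supplied CPI table
(income is input data, not price × production); and the per-year products
of income and fractional change are summed over the decade. The
per-hectare effect divides by mean hectares × number of years by default
(an annualized rate); dividing by mean hectares alone is selectable, as
the convention is ambiguous in common usage.

Frost risk: for each location, shift and threshold (0, −1, −2, −3 °C),
the event "spring frost" is any day with Tmin below the threshold from
emergence (sowing + shift + 15 days) through the spring horizon (default
day-of-year 181); the probability is the plain binomial frequency over a
46-year history. Events nest, so probabilities are monotone in both the
threshold and the shift. The screening rule flags locations strictly
above a 20% cap (9/46 ≈ 0.196 passes; 10/46 ≈ 0.217 fails). The
"any day after emergence" event definition was chosen over
"emergence day only" to match the agronomic recommendation that frost
probabilities be low *on or after* emergence.

## Synthetic study design

The generator fabricates the complete input suite — daily weather for 135
locations (27 states × 5), ~1,350 trials over 2007–2016 with three
maturity groups each, weekly crop-progress ramps, state-year economics,
CPI deflators, and 46-year frost histories — with all ground truth
recorded in `truth.json` before any noise is drawn.

**Planted yield model.** Trial yield = state baseline + 30 kg/ha/yr trend
− 1135 kg/ha/kPa × Vpd(61–90 DAS) − 2074 kg/ha/kPa × (Vpd(30–0 DBS) −
1.79) + 3 kg/ha/mm × (precip(61–90 DAS) − 60 mm) + state-year noise (90)
+ trial noise (200 kg/ha). Crucially, effects are injected through the
same window-feature definitions the pipeline computes, from the actual
generated weather — so recovery failures localize to the inference
stages, not the generator.

**Vpd climatology.** Each state's daily Vpd follows a "moist-period
valley": a parabola in calendar days whose minimum is placed so that
sowing at the state's intended optimal shift centers the 61–90 DAS window
on it. The valley curvature equals the intended yield-response curvature
(1.9 kg/ha/day², softened quadratically for states with |optimum| > 20
days so their curves stay plausible over the grid), saturating 45+|opt|
days out. Spring (pre-sowing) Vpd is a separate flat branch; the two
branches meet at calendar day t0+30, chosen because for every shift in
−30…+30 the pre-sowing window lies entirely before that day and the
61–90 DAS window entirely after it, so neither effect window straddles
the seam. Spring Vpd levels are assigned across states by a balanced
deterministic permutation, uncorrelated with the mid-season Vpd levels
overall and within strata (max |r| = 0.066), so the two planted Vpd
effects are separately identifiable from observational variation — an
experimental-design choice, at the cost of geographic verisimilitude.

Minimum temperatures are obtained by inverting the saturation-vapor-
pressure formula, `Tmin = es⁻¹(es(Tmax) − Vpd_target)`, so the *derived*
Vpd matches the target climatology exactly in expectation; Tmax couples
to the Vpd level (hot when dry) with a floor guaranteeing the target is
achievable and a 55 °C ceiling reached only on saturated-cap days far
outside the effect windows. Vapor pressure follows a dew-point-near-Tmin
model with substantial independent AR(1) humidity variation, so relative
humidity is informative but not a deterministic proxy of Vpd.
Precipitation is Bernoulli wet-day occurrence (wettest near the valley
center) times gamma intensities.

**Truth.** Per state, the expected yield curve is evaluated on a fine
shift grid from the noise-free climatology; its argmax and gain are the
recorded true optimum and gain. The frozen defaults give a
production-weighted mean true optimum of −12.6 days and a weighted
national gain of 9.7% (excluding the two planted later-is-better states,
MS and TX), with per-state optima spanning −30 … +12 days. State incomes
total US$9B/yr so the decade-cumulative monetary effect lands near
US$9–10B. The frost climatology (latitude-driven spring warming, daily
sd 3.8 °C, AR(1) ρ = 0.55) is calibrated so that at a 21-day-earlier
sowing roughly 2% of locations — the coldest northern ones — exceed the
20% cap at 0 °C.

A separate feature-level generator (`gen_tree_structure_dataset`) plants
an explicit partition structure — sharp yield strata at Vpd(61–90 DAS) =
2.44 kPa, pre-sowing Vpd = 1.79 kPa, a two-group state contrast and
precipitation = 75 mm — for testing threshold recovery by the tree,
which a smooth linear-response dataset cannot exercise.

**What the generator does not emulate.** Weather is spatially independent
across locations; the seasonal shapes are stylized (a mid-season Vpd
*dip* engineered to create an interior optimum, flattened radiation
seasonality, large diurnal ranges where deep Vpd is demanded); planted
effects are linear in the features; and all 270 state-years are present,
so the pipeline produces the full 1,890 scenario rows (real multi-state
trial programs have missing state-years). Passing recovery tests
therefore shows the *inference machinery* is correct and well-calibrated
under the planted data-generating process — not that real soybean yields
obey this model, nor that gridded weather is accurate enough at trial
scale (state-level averaging exists precisely because trial-level signal
is weaker).

## Problem sizes and numerical choices

The default study scale (27 × 10 × 5 trials, 365-day years, 46-year
frost histories, 9,999 tree permutations, 600 boosting iterations) runs
the full pipeline in ~25 s on one CPU; the test suite, including a
complete end-to-end recovery run, takes about a minute. Degenerate
inputs are handled explicitly: constant predictors or responses give
permutation p = 1 by convention; trees with fewer than `min_internal`
observations are single leaves; convex response fits fall back to grid
endpoints; zero hectares, missing deflator years, unknown state codes
and daily-coverage gaps raise typed validation errors naming the
offending rows.
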