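# sowshift

Month-specific weather constraints on US soybean yield, and what shifting
sowing dates would have been worth.

Rainfed soybean is highly sensitive to *when* drought stress arrives
relative to crop development. `sowshift` implements an end-to-end analysis
pipeline for multi-state cultivar-trial data aligned with daily gridded
weather:

1. **Window features.** Daily weather is reduced to six successive 30-day
   windows anchored on each trial's sowing date — one pre-sowing window
   (30–0 DBS, days before sowing) and five post-sowing windows (0–150 DAS,
   days after sowing) — plus season-wide totals. Vapor pressure deficit is
   derived as `Vpd = es(Tmax) − es(Tmin)` with
   `es(T) = 0.6107·exp(17.269·T/(237.3 + T))` kPa, and relative humidity
   as `vp / ½(es(Tmax) + es(Tmin))`.
2. **Interpretation.** A conditional-inference regression tree (permutation
   association tests, Bonferroni-adjusted, α = 0.05; node-size and depth
   controls) identifies which window-specific variables partition
   state-year yields, and within-stratum OLS regressions quantify the
   kg/ha-per-kPa yield losses.
3. **Prediction.** A componentwise functional-gradient-descent (L2
   boosting) model predicts state-year yield from all window and season
   features plus coordinates and year (600 iterations, step 0.2),
   evaluated on a held-out split stratified by states within years.
4. **Counterfactuals.** Seven sowing scenarios per state-year (−30 … +30
   days from typical, 10-day steps) are built by sliding the feature
   windows across the unchanged weather; the fitted model simulates yield
   for each — 27 states × 10 years × 7 shifts = 1,890 simulations.
5. **Optima and consequences.** Per-state quadratic response curves (year
   intercepts absorbing the technology trend) yield optimal shifts and
   gains; gains are converted to cumulative inflation-adjusted 2016-US$
   effects, and 46-year Tmin climatologies screen early sowing against a
   20% frost-probability cap at emergence (sowing + 15 days).

Because no trial dataset ships with the package, a first-class synthetic
generator (`sowshift.synthetic_data`) fabricates all inputs with known
planted truth — per-state optimal shifts, Vpd/precipitation effect
coefficients, economics and frost climatologies — so that every stage of
the pipeline is testable by parameter recovery.

## Worked example

```sh
sowshift simulate-data --seed 3 --out data
sowshift run --data data --out results
```

prints the fitted tree to stderr and a summary like:

```json
{
  "national": {
    "mean_optimal_shift_days": -13.86,
    "total_yield_change_pct": 11.22,
    "excluded_states": ["MS", "TX"],
    "n_states": 25
  },
  "economics_national": {
    "cumulative_gain_usd2016": 10637263442.43
  },
  "boost_eval": {"r2": 0.980, "rmse": 124.07},
  "vpd_w3_slope": {
    "slope": -1179.5, "ci_low": -1338.0, "ci_high": -1021.0,
    "n": 169, "homogeneity_p": 0.117
  }
}
```

Reading: excluding the two states whose yields would have benefited from
*later* sowing (MS, TX), sowing ~14 days earlier than typical practice
would have raised production-weighted national yield by ~11%, worth
~US$10.6B cumulatively over the decade in 2016 dollars. Each extra kPa of
vapor pressure deficit during 61–90 DAS cost ≈1,180 kg/ha (95% CI
[−1338, −1021]; the planted generator value is −1,135), with no
significant slope heterogeneity across states (interaction p = 0.12).
Per-state curves, scenario yields, the serialized tree and boosting model,
and frost screening land in `results/`.

The same analysis is available as a library:

```python
from sowshift import synthetic_data, pipeline
from sowshift.io_formats import RunConfig

data = synthetic_data.generate_all(seed=3)
results = pipeline.run_pipeline(data, RunConfig(seed=3))
results["curves"]          # per-state optimum shift and gain
data["truth"]["national"]  # the planted ground truth
```

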