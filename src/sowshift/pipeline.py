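"""End-to-end orchestration of the sowing-shift analysis.

Stages, in the order the method runs: trial pooling → per-trial window
features → state-year averaging → conditional-inference tree (+ within-
stratum Vpd slope regressions) → boosted predictive model with a
stratified train/test evaluation → counterfactual sowing scenarios →
per-state quadratic response optima and the national summary → monetary
effects → frost screening.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from . import (
    boost_model,
    citree,
    counterfactual_sim,
    economics,
    frost_risk,
    trial_prep,
    weather_features as wf,
)
from .io_formats import RunConfig

logger = logging.getLogger(__name__)


def compute_trial_features(trials: pd.DataFrame,
                           weather: pd.DataFrame) -> pd.DataFrame:
    """Sowing-relative window features for every pooled trial row."""
    by_loc_year = {k: g.reset_index(drop=True)
                   for k, g in weather.groupby(["location_id", "year"],
                                               sort=False)}
    coords = weather.groupby("location_id")[["latitude", "longitude"]].first()
    rows = []
    for _, t in trials.iterrows():
        days = by_loc_year[(t["location_id"], t["year"])]
        feats = wf.aggregate_windows(days, int(t["sowing_doy"]))
        row = feats.to_dict()
        row["trial_id"] = t["trial_id"]
        row["latitude"] = float(coords.loc[t["location_id"], "latitude"])
        row["longitude"] = float(coords.loc[t["location_id"], "longitude"])
        rows.append(row)
    return pd.DataFrame(rows)


def build_state_year_table(trials_long: pd.DataFrame,
                           weather: pd.DataFrame) -> pd.DataFrame:
    """Pooled-MG trials + features, averaged to state-year records."""
    pooled = trial_prep.pool_trials(trials_long)
    feats = compute_trial_features(pooled, weather)
    return trial_prep.aggregate_state_year(pooled, feats), pooled


WPRE_HINGE_KPA = 1.79  # pre-sowing Vpd level separating the harsh stratum


def vpd_slope_estimates(state_year: pd.DataFrame) -> dict:
    """Within-stratum Vpd–yield slope regressions.

    The headline 61–90 DAS slope is estimated where pre-sowing Vpd is
    benign (≤ 1.79 kPa), so the harsh-spring penalty cannot confound it;
    the pre-sowing slope is estimated in the complementary harsh stratum.
    The naive full-sample slope is reported alongside for comparison.
    """
    out = {}
    benign = state_year[state_year["vpd_mean_Wpre"] <= WPRE_HINGE_KPA]
    harsh = state_year[state_year["vpd_mean_Wpre"] > WPRE_HINGE_KPA]
    if len(benign) >= 3 and benign["vpd_mean_W3"].nunique() > 1:
        out["vpd_w3_slope"] = citree.node_vpd_slope(benign, "vpd_mean_W3")
    else:
        out["vpd_w3_slope"] = citree.node_vpd_slope(state_year, "vpd_mean_W3")
    out["vpd_w3_slope_full"] = citree.node_vpd_slope(state_year, "vpd_mean_W3")
    if len(harsh) >= 3 and harsh["vpd_mean_Wpre"].nunique() > 1:
        out["vpd_wpre_slope"] = citree.node_vpd_slope(harsh, "vpd_mean_Wpre")
    return out


def run_pipeline(
    data: dict,
    config: Optional[RunConfig] = None,
) -> dict:
    """Run every analysis stage on a data bundle.

    ``data`` must hold frames ``trials`` (long format), ``weather``,
    ``econ``, ``cpi``; optionally ``frost`` (dict of per-location Tmin
    histories) and ``progress``.  Returns a dict of results keyed by stage.
    """
    config = config or RunConfig()
    results: dict = {}

    state_year, pooled = build_state_year_table(data["trials"], data["weather"])
    results["state_year"] = state_year
    results["pooled_trials"] = pooled

    if "progress" in data and data["progress"] is not None \
            and len(data["progress"]):
        fifty = []
        for (st, yr), grp in data["progress"].groupby(["state", "year"]):
            try:
                fifty.append({"state": st, "year": yr,
                              "doy_50pct": trial_prep.interpolate_50pct_sown(grp)})
            except Exception as exc:  # diagnostic only
                logger.warning("50%%-sown interpolation failed for %s %s: %s",
                               st, yr, exc)
        results["fifty_pct_sown"] = pd.DataFrame(fifty)

    # --- interpretation stage: conditional-inference tree -----------------
    tree_X = wf.tree_predictor_frame(state_year)
    controls = citree.CITreeControls(
        alpha=config.tree_alpha, bonferroni=config.tree_bonferroni,
        min_internal=config.tree_min_internal,
        min_terminal=config.tree_min_terminal,
        max_depth=config.tree_max_depth, n_perm=config.tree_n_perm,
        seed=config.seed,
    )
    tree = citree.fit_citree(tree_X, state_year["yield_kg_ha"], controls)
    results["tree"] = tree
    results["tree_text"] = citree.render_text(tree)
    results.update(vpd_slope_estimates(state_year))

    # --- predictive stage: boosting ---------------------------------------
    bcontrols = boost_model.BoostControls(
        n_iter=config.boost_n_iter, step=config.boost_step,
        base_learner=config.boost_base_learner,
        train_frac=config.train_frac, seed=config.seed,
    )
    train, test = boost_model.stratified_split(
        state_year, config.train_frac, strata=("year",), seed=config.seed
    )
    model = boost_model.fit_boost(
        wf.boost_feature_frame(train), train["yield_kg_ha"], bcontrols
    )
    results["boost_model"] = model
    results["boost_eval"] = boost_model.evaluate(
        model, wf.boost_feature_frame(test), test["yield_kg_ha"]
    )
    results["boost_train_eval"] = boost_model.evaluate(
        model, wf.boost_feature_frame(train), train["yield_kg_ha"]
    )

    # --- counterfactual scenarios and response optima ---------------------
    scenarios, scen_errors = counterfactual_sim.run_scenarios(
        pooled, data["weather"], model, config.shift_grid
    )
    results["scenarios"] = scenarios
    results["scenario_errors"] = scen_errors

    curves = response_optimum_fit(scenarios)
    results["curves"] = curves
    weights = (
        data["econ"].groupby("state")["production_t"].mean().to_dict()
    )
    results["national"] = _national(curves, weights, config)

    # --- economics ---------------------------------------------------------
    econ_table, econ_national = economics.economics_table(
        curves, data["econ"], data["cpi"], config.per_ha_denominator
    )
    results["econ_table"] = econ_table
    results["econ_national"] = econ_national

    # --- frost -------------------------------------------------------------
    frost = data.get("frost")
    if frost:
        sow_by_loc = (
            pooled.groupby("location_id")["sowing_doy"].mean().round()
            .astype(int).to_dict()
        )
        shifts = sorted(set(list(config.shift_grid) + [-21]))
        shifts = [s for s in shifts
                  if all(sow_by_loc[loc] + s + config.emergence_das
                         <= config.frost_horizon_doy for loc in frost)]
        profiles = frost_risk.frost_profiles(
            frost, sow_by_loc, shifts, config.frost_thresholds,
            config.frost_horizon_doy, config.emergence_das,
        )
        verdicts, summary = frost_risk.screen_locations(
            profiles, config.frost_cap
        )
        results["frost_profiles"] = verdicts
        results["frost_summary"] = summary

    return results


def response_optimum_fit(scenarios: pd.DataFrame) -> pd.DataFrame:
    from .response_optimum import fit_response

    return fit_response(scenarios)


def _national(curves: pd.DataFrame, weights: dict, config: RunConfig) -> dict:
    from .response_optimum import national_summary

    return national_summary(
        curves, weights,
        exclude_positive_optima=config.exclude_positive_optima,
    )
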