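"""Trial-table preparation: maturity-group pooling and state-year averaging.

Each cultivar trial reports mean yields for several maturity groups (MG);
the analysis keeps the MG with the maximum yield, on the premise that the
year's weather favored that earliness class.  Trial yields and their weather
features are then averaged, unweighted, within each state × year to form the
analysis records.  The 50%-sown date interpolated from weekly crop-progress
reports is diagnostic only: the sowing anchor used everywhere downstream is
the trial-reported sowing date.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError


def select_max_yield_mg(mg_yields: dict[str, float]) -> tuple[str, float]:
    """Highest-yielding maturity group for one trial.

    Returns ``(mg_label, yield)``; ties break to the earliest (lexically
    smallest) MG label.
    """
    if not mg_yields:
        raise ValidationError("select_max_yield_mg: empty maturity-group map")
    best = max(sorted(mg_yields), key=lambda k: mg_yields[k])
    return best, float(mg_yields[best])


def pool_trials(trials_long: pd.DataFrame) -> pd.DataFrame:
    """Collapse the long trial table to one row per trial (max-yield MG)."""
    if trials_long.empty:
        return trials_long.drop(columns=["mg"], errors="ignore")

    def _pick(group: pd.DataFrame) -> pd.Series:
        mg, y = select_max_yield_mg(
            dict(zip(group["mg"].astype(str), group["yield_kg_ha"]))
        )
        row = group.iloc[0]
        return pd.Series({
            "state": row["state"],
            "year": row["year"],
            "location_id": row["location_id"],
            "sowing_doy": row["sowing_doy"],
            "mg": mg,
            "yield_kg_ha": y,
        })

    out = (
        trials_long.groupby("trial_id", sort=True)
        .apply(_pick, include_groups=False)
        .reset_index()
    )
    return out


def interpolate_50pct_sown(progress: pd.DataFrame) -> int:
    """Day-of-year when 50% of a state's hectares were sown.

    ``progress`` holds weekly ``(doy, pct_sown)`` points for one state-year,
    pct non-decreasing.  Linear interpolation between the bracketing weekly
    reports, rounded half-up to an integer doy.
    """
    pts = progress.sort_values("doy")[["doy", "pct_sown"]].to_numpy(dtype=float)
    if len(pts) < 1:
        raise ValidationError("interpolate_50pct_sown: empty series")
    pct = pts[:, 1]
    if np.any(np.diff(pct) < 0):
        raise ValidationError("interpolate_50pct_sown: pct_sown not non-decreasing")
    exact = pts[pct == 50.0]
    if len(exact):
        return int(exact[0, 0])
    if pct.max() < 50.0:
        raise ValidationError("interpolate_50pct_sown: series never reaches 50%")
    if pct.min() > 50.0:
        raise ValidationError("interpolate_50pct_sown: series starts above 50%")
    idx = int(np.searchsorted(pct, 50.0))
    d0, p0 = pts[idx - 1]
    d1, p1 = pts[idx]
    doy = d0 + (50.0 - p0) / (p1 - p0) * (d1 - d0)
    return int(np.floor(doy + 0.5))  # round half-up


def aggregate_state_year(trials: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Average trial yields and features into state-year analysis records.

    ``trials`` is the pooled one-row-per-trial table; ``features`` carries
    one row per ``trial_id`` with numeric feature columns (window features,
    latitude, longitude).  Means are unweighted over trials.  Output columns:
    ``state, year, yield_kg_ha, n_trials, mean_sowing_doy`` plus every
    feature column.
    """
    if not set(trials["trial_id"]) <= set(features["trial_id"]):
        missing = sorted(set(trials["trial_id"]) - set(features["trial_id"]))
        raise ValidationError(f"aggregate_state_year: trials without features {missing[:5]}")
    merged = trials.merge(features, on="trial_id", how="left", suffixes=("", "_f"))
    feat_cols = [c for c in features.columns if c != "trial_id"]
    agg = {c: "mean" for c in feat_cols}
    agg["yield_kg_ha"] = "mean"
    agg["sowing_doy"] = "mean"
    agg["trial_id"] = "count"
    out = (
        merged.groupby(["state", "year"], sort=True)
        .agg(agg)
        .rename(columns={"trial_id": "n_trials", "sowing_doy": "mean_sowing_doy"})
        .reset_index()
    )
    return out
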