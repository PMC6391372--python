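"""Counterfactual sowing-date scenarios over fixed observed weather.

Seven hypothetical sowing dates per state-year — the typical (state-year
mean trial) date shifted by −30..+30 days in 10-day increments — are turned
into sowing-relative feature sets by sliding the aggregation windows across
the unchanged daily weather.  The fitted predictive model then simulates
yield under each scenario; 27 states × 10 years × 7 shifts gives the full
1,890-simulation design.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import weather_features as wf
from .boost_model import BoostModel, predict_boost
from .errors import SowshiftError

logger = logging.getLogger(__name__)

DEFAULT_SHIFTS = (-30, -20, -10, 0, 10, 20, 30)


def shift_features(days: pd.DataFrame, sowing_doy: int, shift: int,
                   **kwargs) -> pd.Series:
    """Window features with the sowing anchor moved by ``shift`` days.

    Identical to :func:`weather_features.aggregate_windows` at anchor
    ``sowing_doy + shift``; the raw weather is untouched.
    """
    return wf.aggregate_windows(days, int(sowing_doy) + int(shift), **kwargs)


def run_scenarios(
    trials: pd.DataFrame,
    weather: pd.DataFrame,
    model: BoostModel,
    shifts: Iterable[int] = DEFAULT_SHIFTS,
) -> tuple[pd.DataFrame, list[dict]]:
    """Simulate yields for every state-year under every sowing shift.

    ``trials`` is the pooled one-row-per-trial table (``state, year,
    location_id, sowing_doy``); ``weather`` the daily table covering every
    trial location-year.  Scenario features are built at the state's
    typical (decade-mean trial) sowing date, per trial location, then
    averaged across that state-year's locations before prediction, so the
    shift grid is anchored identically in every year of a state.

    Returns the scenario frame ``state, year, shift_days,
    pred_yield_kg_ha`` and a list of row-level error records (failed
    feature builds are collected; the run continues).
    """
    shifts = sorted(int(s) for s in shifts)
    by_loc_year = {
        key: grp.reset_index(drop=True)
        for key, grp in weather.groupby(["location_id", "year"], sort=False)
    }
    loc_coords = (
        weather.groupby("location_id")[["latitude", "longitude"]].first()
    )

    typical = trials.groupby("state")["sowing_doy"].mean().round().astype(int)

    rows = []
    errors: list[dict] = []
    for (state, year), grp in trials.groupby(["state", "year"], sort=True):
        anchor = int(typical[state])
        locs = sorted(grp["location_id"].unique())
        for shift in shifts:
            feat_rows = []
            ok_locs = []
            for loc in locs:
                days = by_loc_year.get((loc, year))
                try:
                    if days is None:
                        raise SowshiftError(f"no weather for ({loc}, {year})")
                    feat_rows.append(shift_features(days, anchor, shift))
                    ok_locs.append(loc)
                except SowshiftError as exc:
                    errors.append({"state": state, "year": year,
                                   "shift": shift, "location_id": loc,
                                   "error": str(exc)})
            if not feat_rows:
                continue
            mean_feats = pd.concat(feat_rows, axis=1).mean(axis=1)
            row = mean_feats.to_dict()
            row["latitude"] = float(loc_coords.loc[ok_locs, "latitude"].mean())
            row["longitude"] = float(loc_coords.loc[ok_locs, "longitude"].mean())
            row["year"] = float(year)
            row["state"] = state
            row["shift_days"] = shift
            rows.append(row)
    if errors:
        logger.warning("run_scenarios: %d failed feature build(s)", len(errors))

    frame = pd.DataFrame(rows)
    X = wf.boost_feature_frame(frame)
    frame["pred_yield_kg_ha"] = predict_boost(model, X)
    out = frame[["state", "year", "shift_days", "pred_yield_kg_ha"]].copy()
    out["year"] = out["year"].astype(int)
    return out, errors
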