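"""Spring frost probabilities at emergence for candidate sowing shifts.

Soybean seedlings are frost-sensitive only after emergence, taken as 15
days after sowing.  For each location, sowing shift and minimum-temperature
threshold, the event "spring frost" is scored per history year as any day
from emergence through the spring horizon (default day-of-year 181) with
Tmin below the threshold; the probability is the plain binomial frequency
over the history years.  A screening rule flags locations whose frost
probability exceeds a cap (default 20%, the common sowing recommendation).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

DEFAULT_THRESHOLDS = (0.0, -1.0, -2.0, -3.0)


def frost_probability(
    tmin_history: pd.DataFrame,
    sowing_doy: int,
    shift: int,
    threshold: float,
    horizon_doy: int = 181,
    emergence_das: int = 15,
) -> dict:
    """Binomial frost probability for one location/shift/threshold.

    ``tmin_history`` holds per-year daily minima (columns ``year, doy,
    tmin``); every year must cover emergence..horizon without gaps.
    Returns the probability, the integer event count and the year count.
    """
    emergence = int(sowing_doy) + int(shift) + int(emergence_das)
    if horizon_doy < emergence:
        raise ValidationError(
            f"frost_probability: horizon doy {horizon_doy} before emergence "
            f"doy {emergence}"
        )
    span = set(range(emergence, horizon_doy + 1))
    events = 0
    years = tmin_history["year"].unique()
    for yr in years:
        sub = tmin_history[tmin_history["year"] == yr]
        window = sub[(sub["doy"] >= emergence) & (sub["doy"] <= horizon_doy)]
        if set(window["doy"]) != span:
            raise ValidationError(
                f"frost_probability: year {yr} does not cover "
                f"doys {emergence}..{horizon_doy}"
            )
        if (window["tmin"] < threshold).any():
            events += 1
    n_years = len(years)
    return {
        "probability": events / n_years,
        "frost_years": int(events),
        "n_years": int(n_years),
    }


def frost_profiles(
    histories: dict[str, pd.DataFrame],
    sowing_doys: dict[str, int],
    shifts: Iterable[int],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    horizon_doy: int = 181,
    emergence_das: int = 15,
) -> pd.DataFrame:
    """Frost probability table over locations × shifts × thresholds."""
    shifts = list(shifts)
    rows = []
    for loc, hist in histories.items():
        sow = int(sowing_doys[loc])
        # pivot once per location; equals the per-year loop in
        # frost_probability exactly (integer event counts)
        mat = hist.pivot(index="year", columns="doy", values="tmin")
        doys = mat.columns.to_numpy()
        vals = mat.to_numpy()
        n_years = vals.shape[0]
        for shift in shifts:
            emergence = sow + int(shift) + int(emergence_das)
            if horizon_doy < emergence:
                raise ValidationError(
                    f"frost_profiles: horizon {horizon_doy} before emergence "
                    f"{emergence} at {loc}"
                )
            sel = (doys >= emergence) & (doys <= horizon_doy)
            need = horizon_doy - emergence + 1
            window = vals[:, sel]
            if window.shape[1] != need or np.isnan(window).any():
                raise ValidationError(
                    f"frost_profiles: {loc} does not cover doys "
                    f"{emergence}..{horizon_doy}"
                )
            for thr in thresholds:
                events = int((window < float(thr)).any(axis=1).sum())
                rows.append({
                    "location_id": loc,
                    "shift_days": int(shift),
                    "threshold_c": float(thr),
                    "probability": events / n_years,
                    "n_years": n_years,
                })
    return pd.DataFrame(rows)


def screen_locations(
    profiles: pd.DataFrame, cap: float = 0.20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the probability cap and summarize by shift and threshold.

    Returns the profile table with a boolean ``exceeds_cap`` verdict
    (strictly above the cap fails the screen) and a summary frame with the
    fraction of locations exceeding the cap per (shift, threshold).
    """
    out = profiles.copy()
    out["exceeds_cap"] = out["probability"] > cap
    summary = (
        out.groupby(["shift_days", "threshold_c"])["exceeds_cap"]
        .mean()
        .rename("fraction_exceeding")
        .reset_index()
    )
    return out, summary
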