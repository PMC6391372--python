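"""Vapor-pressure-deficit derivation and sowing-relative window features.

Daily weather is reduced to agronomically meaningful predictors anchored on
the sowing day of each trial: six successive 30-day windows running from 30
days before sowing (DBS) to 150 days after sowing (DAS), plus season-wide
analogues over the whole −30..+149 span.

Vapor pressure deficit (Vpd) is computed as the difference between the
saturation vapor pressure at the daily maximum and at the daily minimum
temperature; relative humidity divides the observed vapor pressure by the
mean of those two saturation values.  Both use the Magnus-type formula

    es(T) = 0.6107 * exp(17.269 * T / (237.3 + T))   [kPa, T in °C]

Window features per window: cumulative precipitation and solar radiation,
means of daily Vpd, Tmax and relative humidity, the count of wet days
(precip > 1 mm, "a"), dry days (precip < 1 mm, "b") and their ratio a/b.
Daily minimum temperature and day length are aggregated and stored but kept
out of the tree predictor set because they confound with the retained
variables.
"""

from __future__ import annotations

import logging
import math
from typing import Optional

import numpy as np
import pandas as pd

from .errors import MissingDaysError, ValidationError

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Window layout: half-open [start, start + 30) offsets relative to sowing.
# The sowing day itself belongs to W1; offset −1 is the last day of Wpre.
# ---------------------------------------------------------------------------

WINDOW_LENGTH = 30
WINDOWS: dict[str, tuple[int, int]] = {
    "Wpre": (-30, 0),
    "W1": (0, 30),
    "W2": (30, 60),
    "W3": (60, 90),
    "W4": (90, 120),
    "W5": (120, 150),
}
SEASON_SPAN = (-30, 150)  # union of all windows
WINDOW_NAMES = list(WINDOWS)
ALL_SCOPES = WINDOW_NAMES + ["season"]

#: variables entering the interpretation-stage tree (5 per window × 6 windows,
#: plus the categorical state column appended by the caller → 31 predictors).
TREE_VARIABLES = ["precip_cum", "srad_cum", "vpd_mean", "tmax_mean", "rh_mean"]
TREE_PREDICTORS = [f"{v}_{w}" for v in TREE_VARIABLES for w in WINDOW_NAMES]

#: variables entering the predictive boosting model (windows + season-wide),
#: extended with wet/dry-day counts and their ratio.
BOOST_VARIABLES = TREE_VARIABLES + ["wet_days", "dry_days", "ab_ratio"]
BOOST_WEATHER_FEATURES = [f"{v}_{s}" for v in BOOST_VARIABLES for s in ALL_SCOPES]

# stored for inspection but excluded from both model feature sets
_EXTRA_VARIABLES = ["tmin_mean", "dayl_mean"]


# ---------------------------------------------------------------------------
# Daily formulas
# ---------------------------------------------------------------------------

def saturation_vapor_pressure(t):
    """Saturation vapor pressure es(T) in kPa for temperature ``t`` in °C.

    Accepts scalars or arrays.  Raises :class:`ValidationError` for
    non-finite input or temperatures outside the physically sensible
    −60..60 °C range.
    """
    arr = np.asanyarray(t, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("saturation_vapor_pressure: non-finite temperature")
    if np.any(arr < -60.0) or np.any(arr > 60.0):
        raise ValidationError(
            "saturation_vapor_pressure: temperature outside −60..60 °C"
        )
    out = 0.6107 * np.exp(17.269 * arr / (237.3 + arr))
    return float(out) if np.isscalar(t) or arr.ndim == 0 else out


def daily_vpd(tmax, tmin):
    """Daily vapor pressure deficit es(Tmax) − es(Tmin), kPa (non-negative)."""
    tmax_a = np.asanyarray(tmax, dtype=float)
    tmin_a = np.asanyarray(tmin, dtype=float)
    if np.any(tmax_a < tmin_a):
        raise ValidationError("daily_vpd: tmax < tmin")
    out = saturation_vapor_pressure(tmax_a) - saturation_vapor_pressure(tmin_a)
    return float(out) if np.isscalar(tmax) and np.isscalar(tmin) else out


def invert_saturation_vapor_pressure(es):
    """Temperature (°C) whose saturation vapor pressure equals ``es`` (kPa).

    Exact inverse of :func:`saturation_vapor_pressure`; used by the synthetic
    weather generator to impose a target Vpd climatology.
    """
    arr = np.asanyarray(es, dtype=float)
    if np.any(arr <= 0):
        raise ValidationError("invert_saturation_vapor_pressure: es must be > 0")
    x = np.log(arr / 0.6107)
    out = 237.3 * x / (17.269 - x)
    return float(out) if np.isscalar(es) or arr.ndim == 0 else out


def daily_relative_humidity(vp, tmax, tmin, *, warn=True):
    """Relative humidity: vp / mean(es(Tmax), es(Tmin)), as a fraction.

    Values above 1 are physically suspect but permitted (gridded vapor
    pressure occasionally exceeds the derived saturation mean); they are
    logged when ``warn`` is set.
    """
    vp_a = np.asanyarray(vp, dtype=float)
    if np.any(vp_a < 0):
        raise ValidationError("daily_relative_humidity: vp must be ≥ 0")
    tmax_a = np.asanyarray(tmax, dtype=float)
    tmin_a = np.asanyarray(tmin, dtype=float)
    if np.any(tmax_a < tmin_a):
        raise ValidationError("daily_relative_humidity: tmax < tmin")
    es_mean = 0.5 * (
        saturation_vapor_pressure(tmax_a) + saturation_vapor_pressure(tmin_a)
    )
    out = vp_a / es_mean
    n_above = int(np.sum(np.asanyarray(out) > 1.0))
    if warn and n_above:
        logger.warning("relative humidity > 1 on %d day(s)", n_above)
    return float(out) if np.isscalar(vp) and np.isscalar(tmax) else out


def window_of(day_offset: int) -> Optional[str]:
    """Window id for a sowing-relative day offset, or None outside −30..149."""
    off = int(day_offset)
    for name, (lo, hi) in WINDOWS.items():
        if lo <= off < hi:
            return name
    return None


# ---------------------------------------------------------------------------
# Window aggregation
# ---------------------------------------------------------------------------

def _ab_ratio(a: float, b: float) -> tuple[float, float]:
    """Wet/dry-day ratio with the documented b=0 convention: a/(b+1), flagged."""
    if b == 0:
        return a / (b + 1.0), 1.0
    return a / b, 0.0


def aggregate_windows(
    days: pd.DataFrame,
    sowing_doy: int,
    *,
    sowing_year: Optional[int] = None,
) -> pd.Series:
    """Aggregate one location-year daily series into sowing-relative features.

    Parameters
    ----------
    days
        Daily records for one location, columns ``doy, tmin, tmax, precip,
        srad, vp`` (``dayl`` and ``year`` optional).  Must cover every day
        from ``sowing_doy − 30`` to ``sowing_doy + 149``; the series may span
        a calendar-year boundary if a ``year`` column is present (365-day
        years, leap day dropped upstream).
    sowing_doy
        Day-of-year of sowing (the anchor; offset 0).
    sowing_year
        Calendar year of sowing; required when ``days`` carries a ``year``
        column with more than one year.

    Returns
    -------
    pandas.Series of window and season features, keyed ``<var>_<window>``.
    """
    if "year" in days.columns and days["year"].nunique() > 1:
        if sowing_year is None:
            raise ValidationError(
                "aggregate_windows: multi-year series requires sowing_year"
            )
        offsets = (
            (days["year"].to_numpy() - int(sowing_year)) * 365
            + days["doy"].to_numpy()
            - int(sowing_doy)
        )
    else:
        offsets = days["doy"].to_numpy() - int(sowing_doy)

    lo, hi = SEASON_SPAN
    mask = (offsets >= lo) & (offsets < hi)
    present = set(offsets[mask].tolist())
    needed = set(range(lo, hi))
    if present != needed or mask.sum() != len(needed):
        missing = needed - present
        if missing:
            raise MissingDaysError(missing)
        raise ValidationError("aggregate_windows: duplicated day offsets in span")

    sub = days.loc[mask].copy()
    sub["offset"] = offsets[mask]
    sub = sub.sort_values("offset")

    tmax = sub["tmax"].to_numpy(dtype=float)
    tmin = sub["tmin"].to_numpy(dtype=float)
    precip = sub["precip"].to_numpy(dtype=float)
    srad = sub["srad"].to_numpy(dtype=float)
    vp = sub["vp"].to_numpy(dtype=float)
    dayl = sub["dayl"].to_numpy(dtype=float) if "dayl" in sub.columns else None

    vpd = daily_vpd(tmax, tmin)
    rh = daily_relative_humidity(vp, tmax, tmin, warn=False)
    off = sub["offset"].to_numpy()

    feats: dict[str, float] = {}

    def _scope(sel: np.ndarray, name: str) -> None:
        n = int(sel.sum())
        a = float(np.sum(precip[sel] > 1.0))
        b = float(np.sum(precip[sel] < 1.0))
        ratio, flag = _ab_ratio(a, b)
        feats[f"precip_cum_{name}"] = float(np.sum(precip[sel]))
        feats[f"srad_cum_{name}"] = float(np.sum(srad[sel]))
        feats[f"vpd_mean_{name}"] = float(np.mean(vpd[sel]))
        feats[f"tmax_mean_{name}"] = float(np.mean(tmax[sel]))
        feats[f"rh_mean_{name}"] = float(np.mean(rh[sel]))
        feats[f"wet_days_{name}"] = a
        feats[f"dry_days_{name}"] = b
        feats[f"ab_ratio_{name}"] = ratio
        feats[f"ab_zero_b_{name}"] = flag
        feats[f"tmin_mean_{name}"] = float(np.mean(tmin[sel]))
        if dayl is not None:
            feats[f"dayl_mean_{name}"] = float(np.mean(dayl[sel]))
        feats[f"n_days_{name}"] = float(n)

    for name, (w_lo, w_hi) in WINDOWS.items():
        _scope((off >= w_lo) & (off < w_hi), name)
    _scope(np.ones_like(off, dtype=bool), "season")

    feats["sowing_doy"] = float(sowing_doy)
    return pd.Series(feats)


def tree_predictor_frame(features: pd.DataFrame) -> pd.DataFrame:
    """The 31-column tree predictor matrix: 30 numeric window features + state.

    ``features`` must carry all window feature columns plus a ``state``
    column; order is variables-major then windows, with ``state`` last.
    """
    missing = [c for c in TREE_PREDICTORS + ["state"] if c not in features.columns]
    if missing:
        raise ValidationError(f"tree_predictor_frame: missing columns {missing}")
    return features[TREE_PREDICTORS + ["state"]].copy()


def boost_feature_frame(features: pd.DataFrame) -> pd.DataFrame:
    """Predictive-stage feature matrix: weather windows + season, coordinates, year."""
    cols = BOOST_WEATHER_FEATURES + ["latitude", "longitude", "year"]
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValidationError(f"boost_feature_frame: missing columns {missing}")
    return features[cols].astype(float).copy()
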