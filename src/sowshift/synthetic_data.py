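"""Synthetic trial, weather, economics and frost inputs with known truth.

The generator fabricates a 27-state × 10-year cultivar-trial design (5
trial locations per state-year, ≈1,350 trials) whose yields respond to
weather only through the same window features the pipeline computes, so
recovery failures localize to the inference stages rather than the
generator.  The planted structure:

- **Vpd climatology.** Each state's daily Vpd follows a "moist-period
  valley": a quadratic dip centered so that sowing at the state's intended
  optimal shift places the critical 61–90 DAS window over the lowest-Vpd
  stretch; earlier or later sowing drags that window onto the drier
  shoulders.  The valley curvature is chosen so the yield response to the
  sowing shift is close to quadratic over the −30..+30 grid.  A separate
  pre-season branch gives spring Vpd a gentle rise with later sowing.
  Minimum temperatures are derived by inverting the saturation-vapor-
  pressure formula so the *derived* Vpd matches the target climatology.
- **Yield.** baseline + technology trend − 1135 kg/ha/kPa × Vpd(61–90 DAS)
  − 2074 kg/ha/kPa × (Vpd(30–0 DBS) − 1.79) + 3 kg/ha/mm ×
  (precip(61–90 DAS) − 60) + state-year and trial noise.  The planted
  slopes echo the per-kPa yield losses this kind of analysis reports.
  Spring Vpd levels are assigned across states independently of the
  mid-season valley parameters so the two Vpd effects are separately
  identifiable from observational variation.
- **Truth.** Before any noise is drawn, the expected yield response curve
  of every state is evaluated on a fine shift grid from the noise-free
  climatology; its argmax and gain are the recorded true optimum and true
  yield gain.  National truths are production-weighted (excluding the two
  states with later-than-typical optima, which mirror early-adopter
  regions).
- **Economics.** State incomes are scaled so a ≈10% weighted national
  yield gain corresponds to a multi-billion-dollar cumulative effect.
- **Frost.** 46-year spring Tmin histories per location, with a
  latitude-driven climatology calibrated so that at a 21-day-earlier
  sowing only a small northern minority of locations exceeds the 20%
  frost-probability screen at 0 °C.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import io_formats, weather_features as wf

# ---------------------------------------------------------------------------
# Planted effect coefficients (scaled to the per-kPa yield losses and
# thresholds this kind of analysis reports for US soybean).
# ---------------------------------------------------------------------------

BETA_VPD_W3 = -1135.0      # kg/ha per kPa, 61–90 DAS window
BETA_VPD_WPRE = -2074.0    # kg/ha per kPa of pre-sowing (30–0 DBS) Vpd
WPRE_REF = 1.79            # kPa; centering constant for the pre-sowing effect
VPD_W3_THRESHOLD = 2.44    # kPa; step used by the tree-structure dataset
BETA_PRECIP_W3 = 3.0       # kg/ha per mm, 61–90 DAS window
PRECIP_REF = 60.0          # mm
TREND = 30.0               # kg/ha per year technology gain
BASE_YIELD = 5000.0        # kg/ha intercept before weather penalties
BASE_YIELD_STATE_SD = 50.0
TRIAL_NOISE_SD = 200.0     # kg/ha within state-year
STATE_YEAR_NOISE_SD = 90.0  # kg/ha shared within state-year

YIELD_CURVATURE = 1.9      # kg/ha/day² of the planted response quadratic
CURVATURE_SOFT_SPAN = 20.0  # days: states with |optimum| beyond this get a
                            # proportionally shallower valley (keeps their
                            # response realistic over the −30..+30 grid)
U_CAP = 75.0               # days: valley parabola saturates beyond this
K_SP = 0.0              # kPa/day rise of spring Vpd with later sowing
W3_CENTER = 74.5           # days after sowing: center of the 61–90 DAS window

SOWING_JITTER_SD = 9.0     # days, trial-to-trial sowing spread
N_LOCATIONS_PER_STATE = 5
YEARS = tuple(range(2007, 2017))
FROST_YEARS = tuple(range(1971, 2017))[-46:]  # 46-year climatology

# per-state parameters:
#   weight  – production weight (million tonnes scale, national total ≈ 93)
#   t0      – typical sowing day-of-year
#   opt     – designed optimal sowing shift (days; the valley placement)
#   ar      – valley-floor Vpd level for the 61–90 DAS window (kPa)
#   sp      – spring (pre-sowing) Vpd level (kPa)
#   lat/lon – nominal coordinates
STATE_PARAMS: dict[str, dict] = {
    "IL": dict(weight=14.0, t0=130, opt=-11, ar=1.30, sp=2.20, lat=40.0, lon=-89.2),
    "IA": dict(weight=13.0, t0=132, opt=-9, ar=1.35, sp=1.55, lat=42.0, lon=-93.5),
    "MN": dict(weight=9.0, t0=135, opt=-14, ar=1.20, sp=1.28, lat=45.0, lon=-94.3),
    "IN": dict(weight=7.5, t0=130, opt=-11, ar=1.25, sp=2.10, lat=40.0, lon=-86.3),
    "NE": dict(weight=7.0, t0=132, opt=-8, ar=1.50, sp=1.70, lat=41.0, lon=-98.0),
    "OH": dict(weight=6.5, t0=130, opt=-10, ar=1.20, sp=1.35, lat=40.2, lon=-83.0),
    "MO": dict(weight=5.5, t0=125, opt=-13, ar=1.50, sp=1.55, lat=38.5, lon=-92.5),
    "SD": dict(weight=5.0, t0=135, opt=-15, ar=1.45, sp=1.30, lat=44.5, lon=-99.5),
    "ND": dict(weight=4.5, t0=138, opt=-18, ar=1.35, sp=1.60, lat=47.5, lon=-99.8),
    "KS": dict(weight=4.0, t0=125, opt=-13, ar=1.65, sp=1.30, lat=38.5, lon=-98.0),
    "AR": dict(weight=3.3, t0=115, opt=-20, ar=1.40, sp=1.25, lat=35.0, lon=-92.0),
    "MS": dict(weight=2.3, t0=105, opt=6, ar=1.30, sp=2.15, lat=32.5, lon=-90.0),
    "MI": dict(weight=2.2, t0=132, opt=-8, ar=1.05, sp=1.40, lat=43.0, lon=-84.7),
    "KY": dict(weight=2.0, t0=125, opt=-12, ar=1.25, sp=1.40, lat=37.5, lon=-85.5),
    "WI": dict(weight=2.0, t0=132, opt=-7, ar=1.10, sp=2.20, lat=44.0, lon=-89.8),
    "TN": dict(weight=1.7, t0=120, opt=-18, ar=1.35, sp=2.25, lat=35.8, lon=-86.5),
    "LA": dict(weight=1.5, t0=105, opt=-25, ar=1.30, sp=1.45, lat=31.0, lon=-92.0),
    "NC": dict(weight=1.0, t0=120, opt=-27, ar=1.30, sp=1.95, lat=35.5, lon=-79.5),
    "VA": dict(weight=0.7, t0=120, opt=-27, ar=1.20, sp=2.30, lat=37.5, lon=-77.8),
    "PA": dict(weight=0.6, t0=130, opt=-9, ar=1.15, sp=1.30, lat=40.8, lon=-77.5),
    "OK": dict(weight=0.5, t0=120, opt=-20, ar=1.75, sp=2.05, lat=35.5, lon=-97.3),
    "AL": dict(weight=0.5, t0=115, opt=-29, ar=1.25, sp=2.05, lat=32.8, lon=-86.8),
    "GA": dict(weight=0.45, t0=115, opt=-29, ar=1.30, sp=1.38, lat=32.5, lon=-83.5),
    "SC": dict(weight=0.4, t0=115, opt=-28, ar=1.35, sp=2.25, lat=34.0, lon=-81.0),
    "TX": dict(weight=0.4, t0=100, opt=12, ar=1.10, sp=1.55, lat=31.0, lon=-97.5),
    "DE": dict(weight=0.2, t0=130, opt=-21, ar=1.20, sp=1.45, lat=39.0, lon=-75.5),
    "FL": dict(weight=0.1, t0=115, opt=-29, ar=1.20, sp=1.40, lat=30.5, lon=-84.3),
}
POSITIVE_OPTIMUM_STATES = ("MS", "TX")

NATIONAL_INCOME_PER_YEAR = 9.0e9  # US$, so a ~10% decade gain is ~US$9B


# ---------------------------------------------------------------------------
# Climatology (noise-free seasonal means)
# ---------------------------------------------------------------------------

def _valley_center(p: dict) -> float:
    return p["t0"] + p["opt"] + W3_CENTER


def state_curvature(p: dict) -> float:
    """Planted yield-response curvature (kg/ha/day²) for one state."""
    scale = min(1.0, (CURVATURE_SOFT_SPAN / max(abs(p["opt"]), 1.0)) ** 2)
    return YIELD_CURVATURE * scale


def vpd_climatology(doy, p: dict) -> np.ndarray:
    """Target daily Vpd (kPa): moist-period valley + spring branch."""
    d = np.asarray(doy, dtype=float)
    u = d - _valley_center(p)
    c_v = state_curvature(p) / abs(BETA_VPD_W3)
    u_cap = min(45.0 + abs(p["opt"]), U_CAP)
    main = p["ar"] + c_v * np.minimum(u ** 2, u_cap ** 2)
    spring = p["sp"] + K_SP * (d - (p["t0"] - 15.5))
    # The two branches meet at calendar day t0+30: for every shift in
    # −30..+30 the pre-sowing window lies entirely before it and the
    # 61–90 DAS window entirely after, so neither effect window ever
    # straddles the seam.
    wgt = np.clip(d - (p["t0"] + 29.0), 0.0, 1.0)
    out = (1 - wgt) * spring + wgt * main
    return np.maximum(out, 0.15)


def tmax_climatology(doy, p: dict) -> np.ndarray:
    """Seasonal daily-maximum temperature coupled to the Vpd level."""
    d = np.asarray(doy, dtype=float)
    base = 25.0 - 0.45 * (p["lat"] - 38.0) + 5.0 * np.sin(
        2 * np.pi * (d - 110.0) / 365.0
    )
    vpd = vpd_climatology(d, p)
    # hot when dry, and never so cool that es(tmax) cannot support the
    # target Vpd (the floor would otherwise truncate the climatology)
    warm = base + 3.0 * np.maximum(vpd - 1.0, 0.0)
    out = np.maximum(warm, wf.invert_saturation_vapor_pressure(vpd + 0.45))
    # physical ceiling; only saturated-cap days far outside the effect
    # windows ever reach it
    return np.minimum(out, 55.0)


def tmin_climatology(doy, p: dict) -> np.ndarray:
    """Daily-minimum temperature that reproduces the target Vpd exactly."""
    tmax = tmax_climatology(doy, p)
    es_max = wf.saturation_vapor_pressure(tmax)
    es_min = np.maximum(es_max - vpd_climatology(doy, p), 0.12)
    return wf.invert_saturation_vapor_pressure(es_min)


def wet_day_probability(doy, p: dict) -> np.ndarray:
    d = np.asarray(doy, dtype=float)
    u = d - _valley_center(p)
    return 0.30 + 0.12 * np.exp(-(u ** 2) / (2 * 45.0 ** 2))


PRECIP_MEAN_WET = 7.0      # mm per wet day (gamma mean)
PRECIP_GAMMA_SHAPE = 0.7


def day_length_seconds(doy, lat: float) -> np.ndarray:
    """Astronomical day length (s) from solar declination and latitude."""
    d = np.asarray(doy, dtype=float)
    decl = np.deg2rad(23.44) * np.sin(2 * np.pi * (d - 81.0) / 365.0)
    lat_r = np.deg2rad(lat)
    cos_h = np.clip(-np.tan(lat_r) * np.tan(decl), -1.0, 1.0)
    return 86400.0 * np.arccos(cos_h) / np.pi


def climatology_frame(p: dict, year: int = 2011,
                      location_id: str = "clim") -> pd.DataFrame:
    """Noise-free daily weather for one synthetic location-year.

    Wet-day precipitation is replaced by its expectation, so cumulative
    precipitation (the only precipitation quantity with a planted yield
    effect) matches its mean.
    """
    doy = np.arange(1, 366)
    tmax = tmax_climatology(doy, p)
    tmin = tmin_climatology(doy, p)
    precip = wet_day_probability(doy, p) * PRECIP_MEAN_WET
    srad = np.maximum(17.0 + 2.0 * np.sin(2 * np.pi * (doy - 110.0) / 365.0), 1.0)
    vp = 0.92 * wf.saturation_vapor_pressure(tmin)
    return pd.DataFrame({
        "location_id": location_id,
        "latitude": p["lat"], "longitude": p["lon"],
        "year": year, "doy": doy,
        "tmin": tmin, "tmax": tmax, "precip": precip,
        "srad": srad, "vp": vp,
        "dayl": day_length_seconds(doy, p["lat"]),
    })


# ---------------------------------------------------------------------------
# Noisy daily weather
# ---------------------------------------------------------------------------

def _ar1(n: int, sd: float, rho: float, rng: np.random.Generator) -> np.ndarray:
    eps = rng.normal(0.0, sd * np.sqrt(1 - rho ** 2), n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + eps[i]
    return out


def gen_daily_weather(
    p: dict, years: Iterable[int], rng: np.random.Generator,
    location_id: str, latitude: Optional[float] = None,
    longitude: Optional[float] = None,
) -> pd.DataFrame:
    """Noisy daily weather series for one location over several years.

    Temperatures are the seasonal climatology plus autocorrelated noise
    (Tmin correlated with Tmax, never exceeding it); precipitation is a
    Bernoulli wet-day occurrence times gamma intensities; vapor pressure
    follows a dew-point-near-Tmin model.
    """
    lat = p["lat"] if latitude is None else latitude
    lon = p["lon"] if longitude is None else longitude
    frames = []
    doy = np.arange(1, 366)
    tmax_c = tmax_climatology(doy, p)
    tmin_c = tmin_climatology(doy, p)
    pw = wet_day_probability(doy, p)
    srad_c = np.maximum(17.0 + 2.0 * np.sin(2 * np.pi * (doy - 110.0) / 365.0), 1.0)
    dayl = day_length_seconds(doy, lat)
    for year in years:
        shared = _ar1(365, 2.8, 0.6, rng)
        tmax = tmax_c + shared + _ar1(365, 1.2, 0.3, rng)
        tmin = tmin_c + 0.8 * shared + _ar1(365, 1.2, 0.3, rng)
        tmax = np.clip(tmax, -55.0, 58.0)
        tmin = np.clip(np.minimum(tmin, tmax - 0.3), -55.0, None)
        wet = rng.random(365) < pw
        amounts = rng.gamma(PRECIP_GAMMA_SHAPE,
                            PRECIP_MEAN_WET / PRECIP_GAMMA_SHAPE, 365)
        precip = np.where(wet, amounts, 0.0)
        srad = np.maximum(srad_c + rng.normal(0, 2.0, 365), 0.5)
        # dew point near Tmin on average, but with substantial independent
        # humidity variation so RH is not a deterministic proxy of Vpd
        humid = np.clip(1.0 + _ar1(365, 0.18, 0.5, rng), 0.55, 1.35)
        vp = np.maximum(0.92 * wf.saturation_vapor_pressure(tmin) * humid, 0.05)
        frames.append(pd.DataFrame({
            "location_id": location_id, "latitude": lat, "longitude": lon,
            "year": year, "doy": doy,
            "tmin": tmin, "tmax": tmax, "precip": precip,
            "srad": srad, "vp": vp, "dayl": dayl,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Yield model and truth
# ---------------------------------------------------------------------------

def yield_from_features(feats: pd.Series, base: float, year: float) -> float:
    """Deterministic yield (kg/ha) from planted window-feature effects."""
    return float(
        base
        + TREND * (year - YEARS[0])
        + BETA_VPD_W3 * feats["vpd_mean_W3"]
        + BETA_VPD_WPRE * (feats["vpd_mean_Wpre"] - WPRE_REF)
        + BETA_PRECIP_W3 * (feats["precip_cum_W3"] - PRECIP_REF)
    )


def expected_response_curve(
    state: str, shifts: Sequence[int] = tuple(range(-30, 31)),
) -> pd.DataFrame:
    """Noise-free expected yield at each sowing shift for one state."""
    p = STATE_PARAMS[state]
    clim = climatology_frame(p)
    rows = []
    for s in shifts:
        feats = wf.aggregate_windows(clim, p["t0"] + int(s))
        rows.append({
            "shift_days": int(s),
            "expected_yield": yield_from_features(
                feats, BASE_YIELD, np.mean(YEARS)
            ),
        })
    return pd.DataFrame(rows)


def build_truth() -> dict:
    """Planted ground truth, evaluated before any noise is drawn."""
    per_state = {}
    for state, p in STATE_PARAMS.items():
        curve = expected_response_curve(state)
        y = curve["expected_yield"].to_numpy()
        s = curve["shift_days"].to_numpy()
        i_opt = int(np.argmax(y))
        y0 = float(y[s == 0][0])
        per_state[state] = {
            "designed_vertex_days": p["opt"],
            "true_optimum_days": int(s[i_opt]),
            "true_gain_kg_ha": float(y[i_opt] - y0),
            "true_gain_fraction": float((y[i_opt] - y0) / y0),
            "expected_yield_at_zero": y0,
            "production_weight": p["weight"],
        }
    sel = {s: v for s, v in per_state.items()
           if s not in POSITIVE_OPTIMUM_STATES}
    w = np.array([v["production_weight"] for v in sel.values()])
    opts = np.array([v["true_optimum_days"] for v in sel.values()])
    gains = np.array([v["true_gain_fraction"] for v in sel.values()])
    return {
        "coefficients": {
            "beta_vpd_w3": BETA_VPD_W3,
            "beta_vpd_wpre": BETA_VPD_WPRE,
            "wpre_reference_kpa": WPRE_REF,
            "beta_precip_w3": BETA_PRECIP_W3,
            "trend_kg_ha_yr": TREND,
            "yield_curvature_kg_ha_day2": YIELD_CURVATURE,
        },
        "noise": {
            "trial_sd": TRIAL_NOISE_SD,
            "state_year_sd": STATE_YEAR_NOISE_SD,
            "base_yield_state_sd": BASE_YIELD_STATE_SD,
        },
        "per_state": per_state,
        "national": {
            "weighted_mean_optimum_days": float(np.sum(w * opts) / np.sum(w)),
            "weighted_gain_pct": float(100 * np.sum(w * gains) / np.sum(w)),
            "excluded_states": list(POSITIVE_OPTIMUM_STATES),
        },
    }


# ---------------------------------------------------------------------------
# Trials, economics, crop progress, frost
# ---------------------------------------------------------------------------

def gen_trials(
    weather: pd.DataFrame,
    base_yields: dict[str, float],
    rng: np.random.Generator,
    years: Sequence[int] = YEARS,
) -> pd.DataFrame:
    """Long-format trial table; yields respond to the actual generated weather.

    Every trial grows three maturity groups with one dominant (the planted
    yield) and two suppressed alternatives.
    """
    by_loc_year = {k: g.reset_index(drop=True)
                   for k, g in weather.groupby(["location_id", "year"], sort=False)}
    locs_by_state: dict[str, list[str]] = {}
    for loc in weather["location_id"].unique():
        locs_by_state.setdefault(loc.split("_")[0], []).append(loc)

    rows = []
    for state, p in STATE_PARAMS.items():
        for year in years:
            sy_noise = rng.normal(0.0, STATE_YEAR_NOISE_SD)
            for loc in sorted(locs_by_state[state]):
                delta = int(np.clip(round(rng.normal(0.0, SOWING_JITTER_SD)),
                                    -18, 18))
                sow = p["t0"] + delta
                feats = wf.aggregate_windows(by_loc_year[(loc, year)], sow)
                y = (
                    yield_from_features(feats, base_yields[state], year)
                    + sy_noise
                    + rng.normal(0.0, TRIAL_NOISE_SD)
                )
                y = max(y, 150.0)
                trial_id = f"{loc}_{year}"
                mg_main = "MG3" if p["lat"] < 41 else "MG2"
                mg_alt = ["MG1", "MG4"]
                rows.append(dict(trial_id=trial_id, state=state, year=year,
                                 location_id=loc, sowing_doy=sow,
                                 mg=mg_main, yield_kg_ha=round(y, 1)))
                for mg in mg_alt:
                    rows.append(dict(
                        trial_id=trial_id, state=state, year=year,
                        location_id=loc, sowing_doy=sow, mg=mg,
                        yield_kg_ha=round(max(y - rng.uniform(100, 400), 100.0), 1),
                    ))
    return pd.DataFrame(rows)


def gen_crop_progress(rng: np.random.Generator,
                      years: Sequence[int] = YEARS) -> pd.DataFrame:
    """Weekly percent-sown reports: a logistic ramp around each typical date."""
    rows = []
    for state, p in STATE_PARAMS.items():
        for year in years:
            mid = p["t0"] + rng.normal(0, 2.0)
            for doy in range(p["t0"] - 28, p["t0"] + 29, 7):
                pct = 100.0 / (1.0 + np.exp(-(doy - mid) / 4.5))
                rows.append(dict(state=state, year=year, doy=doy,
                                 pct_sown=round(float(np.clip(pct, 0, 100)), 1)))
    return pd.DataFrame(rows)


def gen_econ_tables(
    rng: np.random.Generator, years: Sequence[int] = YEARS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """State-year income/production/hectares and a CPI deflator table."""
    total_w = sum(p["weight"] for p in STATE_PARAMS.values())
    rows = []
    for state, p in STATE_PARAMS.items():
        share = p["weight"] / total_w
        for year in years:
            wiggle = 1.0 + rng.normal(0.0, 0.05)
            production = p["weight"] * 1.0e6 * wiggle
            rows.append(dict(
                state=state, year=year,
                income_usd=round(NATIONAL_INCOME_PER_YEAR * share * wiggle, 2),
                production_t=round(production, 1),
                hectares=round(production / 2.9, 1),
            ))
    econ = pd.DataFrame(rows)
    cpi = pd.DataFrame({
        "year": list(years),
        "deflator_to_2016": [round(1.0 + 0.018 * (2016 - y), 4) for y in years],
    })
    return econ, cpi


# frost climatology: spring Tmin warms linearly through the season; the
# intercept drops with latitude so only the coldest northern locations
# stay risky at a 21-day-earlier sowing.
FROST_WARMING_RATE = 0.22      # °C per day through spring
FROST_TMIN_SD = 3.8            # daily noise, °C
FROST_RHO = 0.55               # day-to-day autocorrelation
FROST_BASE_AT_45 = 7.1         # mean Tmin (°C) at doy 120 for latitude 45


def spring_tmin_mean(doy, lat: float) -> np.ndarray:
    d = np.asarray(doy, dtype=float)
    return FROST_BASE_AT_45 - 1.05 * (lat - 45.0) + FROST_WARMING_RATE * (d - 120.0)


def gen_frost_histories(
    locations: pd.DataFrame,
    rng: np.random.Generator,
    years: Sequence[int] = FROST_YEARS,
    doy_range: tuple[int, int] = (60, 185),
) -> dict[str, pd.DataFrame]:
    """46-year spring Tmin histories per location (long frames)."""
    lo, hi = doy_range
    doy = np.arange(lo, hi + 1)
    out = {}
    for _, row in locations.iterrows():
        mean = spring_tmin_mean(doy, row["latitude"])
        cold_offset = rng.normal(0.0, 0.9)
        frames = []
        for yr in years:
            tmin = mean + cold_offset + _ar1(len(doy), FROST_TMIN_SD,
                                             FROST_RHO, rng)
            frames.append(pd.DataFrame({"year": yr, "doy": doy, "tmin": tmin}))
        out[row["location_id"]] = pd.concat(frames, ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# Feature-level dataset with explicit tree structure
# ---------------------------------------------------------------------------

FIG2_GROUP2 = ("AR", "DE", "IL", "IN", "KY", "MI", "MS", "NE", "OH", "PA",
               "SD", "SC", "WI")


def gen_tree_structure_dataset(n: int = 186, seed: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """State-year-style predictor matrix with a planted partition structure.

    Yields follow four strata defined by Vpd(61–90 DAS) at 2.44 kPa,
    pre-sowing Vpd at 1.79 kPa, a two-group state contrast and
    precipitation(61–90 DAS) at 75 mm, with sharp between-stratum mean
    differences — the configuration a conditional-inference tree should
    recover, first split included.  Returns (X, y) where X carries the full
    31-predictor tree schema.
    """
    rng = np.random.default_rng(seed)
    states = rng.choice(io_formats.US_SOY_STATES, size=n)
    X = pd.DataFrame(index=range(n))
    for var in wf.TREE_VARIABLES:
        for w in wf.WINDOW_NAMES:
            col = f"{var}_{w}"
            if var == "vpd_mean":
                X[col] = rng.uniform(0.8, 3.2, n)
            elif var == "precip_cum":
                X[col] = rng.uniform(20.0, 140.0, n)
            elif var == "srad_cum":
                X[col] = rng.uniform(300.0, 700.0, n)
            elif var == "tmax_mean":
                X[col] = rng.uniform(15.0, 34.0, n)
            else:
                X[col] = rng.uniform(0.35, 0.9, n)
    X["vpd_mean_W3"] = rng.uniform(1.2, 3.6, n)
    X["vpd_mean_Wpre"] = rng.uniform(1.1, 2.6, n)
    X["precip_cum_W3"] = rng.uniform(30.0, 130.0, n)
    X["state"] = states

    in_g2 = np.isin(states, FIG2_GROUP2)
    hi_vpd = X["vpd_mean_W3"].to_numpy() > VPD_W3_THRESHOLD
    hi_pre = X["vpd_mean_Wpre"].to_numpy() > WPRE_REF
    wet = X["precip_cum_W3"].to_numpy() > 75.0
    mu = np.where(
        hi_vpd,
        np.where(hi_pre, 1500.0, 2300.0),
        np.where(in_g2, 4400.0, np.where(wet, 3900.0, 3100.0)),
    )
    y = mu + rng.normal(0.0, 300.0, n)
    return X, y


# ---------------------------------------------------------------------------
# Full dataset assembly
# ---------------------------------------------------------------------------

def generate_all(
    seed: int,
    out_dir=None,
    years: Sequence[int] = YEARS,
    n_locations: int = N_LOCATIONS_PER_STATE,
    with_frost: bool = True,
) -> dict:
    """Generate every pipeline input plus the recorded truth.

    Returns a dict with keys ``weather, trials, progress, econ, cpi,
    locations, frost (dict of frames), truth``; when ``out_dir`` is given,
    everything is also written as CSV (+ ``truth.json``).
    """
    rng = np.random.default_rng(seed)
    truth = build_truth()

    loc_rows = []
    for state, p in STATE_PARAMS.items():
        for k in range(n_locations):
            loc_rows.append(dict(
                location_id=f"{state}_L{k + 1}",
                state=state,
                latitude=round(p["lat"] + rng.uniform(-1.0, 1.0), 3),
                longitude=round(p["lon"] + rng.uniform(-1.5, 1.5), 3),
            ))
    locations = pd.DataFrame(loc_rows)

    weather_frames = []
    for _, row in locations.iterrows():
        p = STATE_PARAMS[row["state"]]
        weather_frames.append(gen_daily_weather(
            p, years, rng, row["location_id"],
            latitude=row["latitude"], longitude=row["longitude"],
        ))
    weather = pd.concat(weather_frames, ignore_index=True)

    base_yields = {
        state: BASE_YIELD + rng.normal(0.0, BASE_YIELD_STATE_SD)
        for state in STATE_PARAMS
    }
    truth["base_yields"] = {s: float(v) for s, v in base_yields.items()}

    trials = gen_trials(weather, base_yields, rng, years)
    progress = gen_crop_progress(rng, years)
    econ, cpi = gen_econ_tables(rng, years)
    frost = gen_frost_histories(locations, rng) if with_frost else {}

    out = dict(weather=weather, trials=trials, progress=progress,
               econ=econ, cpi=cpi, locations=locations, frost=frost,
               truth=truth)
    if out_dir is not None:
        path = Path(out_dir)
        path.mkdir(parents=True, exist_ok=True)
        io_formats.write_daily_weather(weather, path / "weather.csv")
        trials.to_csv(path / "trials.csv", index=False)
        progress.to_csv(path / "crop_progress.csv", index=False)
        econ.to_csv(path / "economics.csv", index=False)
        cpi.to_csv(path / "cpi.csv", index=False)
        locations.to_csv(path / "locations.csv", index=False)
        if frost:
            pd.concat(
                [df.assign(location_id=loc) for loc, df in frost.items()],
                ignore_index=True,
            ).to_csv(path / "frost_tmin.csv", index=False)
        with open(path / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
    return out
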