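"""Tabular input/output, schema validation and run configuration.

All tables are plain delimited text (CSV with header rows).  Schemas:

- daily weather: ``location_id,latitude,longitude,year,doy,tmin_c,tmax_c,
  precip_mm,srad,vp,dayl_s`` — vapor pressure may arrive in Pa (Daymet
  convention) or kPa; the reader converts to kPa via an explicit flag.
- trials (long): ``trial_id,state,year,location_id,sowing_doy,mg,yield_kg_ha``
- crop progress: ``state,year,doy,pct_sown``
- economics: ``state,year,income_usd,production_t,hectares``
- CPI deflators: ``year,deflator_to_2016``

Leap-day rows (doy 366) are dropped with a logged count so that every year
has exactly 365 day slots, keeping sowing-relative window arithmetic uniform.
Gaps in daily coverage are rejected downstream rather than imputed.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

US_SOY_STATES = [
    "AL", "AR", "DE", "FL", "GA", "IA", "IL", "IN", "KS", "KY", "LA", "MI",
    "MN", "MO", "MS", "NC", "ND", "NE", "OH", "OK", "PA", "SC", "SD", "TN",
    "TX", "VA", "WI",
]

WEATHER_COLUMNS = [
    "location_id", "latitude", "longitude", "year", "doy",
    "tmin_c", "tmax_c", "precip_mm", "srad", "vp", "dayl_s",
]
TRIAL_COLUMNS = [
    "trial_id", "state", "year", "location_id", "sowing_doy", "mg", "yield_kg_ha",
]
PROGRESS_COLUMNS = ["state", "year", "doy", "pct_sown"]
ECON_COLUMNS = ["state", "year", "income_usd", "production_t", "hectares"]
CPI_COLUMNS = ["year", "deflator_to_2016"]

# internal short names used throughout the pipeline
_WEATHER_RENAME = {"tmin_c": "tmin", "tmax_c": "tmax", "precip_mm": "precip",
                   "dayl_s": "dayl"}


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def read_daily_weather(path, vp_unit: str = "kPa") -> pd.DataFrame:
    """Read a daily-weather CSV into the internal record frame.

    Returns a frame sorted by ``(location_id, year, doy)`` with columns
    ``location_id, latitude, longitude, year, doy, tmin, tmax, precip, srad,
    vp, dayl`` and vp expressed in kPa.
    """
    if vp_unit not in ("Pa", "kPa"):
        raise ValueError(f"vp_unit must be 'Pa' or 'kPa', got {vp_unit!r}")
    df = pd.read_csv(path)
    _require_columns(df, WEATHER_COLUMNS, "daily weather")
    df = df.rename(columns=_WEATHER_RENAME)

    n_leap = int((df["doy"] == 366).sum())
    if n_leap:
        logger.warning("dropping %d leap-day (doy 366) row(s)", n_leap)
        df = df[df["doy"] != 366]

    bad_doy = df[(df["doy"] < 1) | (df["doy"] > 365)]
    if len(bad_doy):
        raise ValidationError(
            f"daily weather: doy outside 1..365 at rows {bad_doy.index[:5].tolist()}"
        )
    bad = df[df["tmax"] < df["tmin"]]
    if len(bad):
        raise ValidationError(
            f"daily weather: tmax < tmin at row(s) {bad.index[:5].tolist()}"
        )
    if (df["precip"] < 0).any():
        raise ValidationError("daily weather: negative precipitation")
    if (df["vp"] < 0).any():
        raise ValidationError("daily weather: negative vapor pressure")
    dup = df.duplicated(subset=["location_id", "year", "doy"])
    if dup.any():
        raise ValidationError(
            f"daily weather: duplicate (location_id, year, doy) at "
            f"row(s) {df.index[dup][:5].tolist()}"
        )
    if vp_unit == "Pa":
        df = df.assign(vp=df["vp"] / 1000.0)
    return df.sort_values(["location_id", "year", "doy"]).reset_index(drop=True)


def write_daily_weather(df: pd.DataFrame, path, vp_unit: str = "kPa") -> None:
    out = df.rename(columns={v: k for k, v in _WEATHER_RENAME.items()}).copy()
    if vp_unit == "Pa":
        out["vp"] = out["vp"] * 1000.0
    out[WEATHER_COLUMNS].to_csv(path, index=False)


def read_trials(path, known_states: Iterable[str] = US_SOY_STATES) -> pd.DataFrame:
    """Read the long-format trial table (one row per trial × maturity group)."""
    df = pd.read_csv(path)
    _require_columns(df, TRIAL_COLUMNS, "trials")
    if df.empty:
        return df
    unknown = sorted(set(df["state"]) - set(known_states))
    if unknown:
        raise ValidationError(f"trials: unknown state code(s) {unknown}")
    if (df["yield_kg_ha"] <= 0).any():
        raise ValidationError("trials: non-positive yield")
    if ((df["sowing_doy"] < 1) | (df["sowing_doy"] > 200)).any():
        raise ValidationError("trials: sowing_doy outside 1..200")
    return df


def read_crop_progress(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, PROGRESS_COLUMNS, "crop progress")
    if ((df["pct_sown"] < 0) | (df["pct_sown"] > 100)).any():
        raise ValidationError("crop progress: pct_sown outside 0..100")
    return df


def read_state_tables(econ_path, cpi_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the per-state-year economics table and the CPI deflator table."""
    econ = pd.read_csv(econ_path)
    _require_columns(econ, ECON_COLUMNS, "economics")
    unknown = sorted(set(econ["state"]) - set(US_SOY_STATES))
    if unknown:
        raise ValidationError(f"economics: unknown state code(s) {unknown}")
    cpi = pd.read_csv(cpi_path)
    _require_columns(cpi, CPI_COLUMNS, "cpi")
    return econ, cpi


def check_econ_coverage(econ: pd.DataFrame, state_years: pd.DataFrame) -> None:
    """Fail if a (state, year) required by the analysis lacks an economics row."""
    need = set(map(tuple, state_years[["state", "year"]].drop_duplicates().values))
    have = set(map(tuple, econ[["state", "year"]].drop_duplicates().values))
    missing = sorted(need - have)
    if missing:
        raise ValidationError(f"economics: missing (state, year) pair(s) {missing[:10]}")


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_outputs(results: dict[str, pd.DataFrame], out_dir) -> None:
    """Write every result frame as ``<name>.csv`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in results.items():
        write_table(df, out / f"{name}.csv")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Configuration for a full pipeline run (YAML-mirrorable)."""

    window_length: int = 30
    pre_sowing_windows: int = 1
    post_sowing_windows: int = 5
    # conditional-inference tree controls
    tree_alpha: float = 0.05
    tree_bonferroni: bool = True
    tree_min_internal: int = 38     # > 37 observations to attempt a split
    tree_min_terminal: int = 19     # > 18 observations per leaf
    tree_max_depth: int = 10
    tree_n_perm: int = 9999
    # boosting controls
    boost_n_iter: int = 600
    boost_step: float = 0.2
    boost_base_learner: str = "componentwise_linear"
    train_frac: float = 0.85
    # counterfactual grid and frost screening
    shift_grid: tuple[int, ...] = (-30, -20, -10, 0, 10, 20, 30)
    frost_thresholds: tuple[float, ...] = (0.0, -1.0, -2.0, -3.0)
    frost_horizon_doy: int = 181
    frost_cap: float = 0.20
    emergence_das: int = 15
    # misc
    seed: int = 0
    per_ha_denominator: str = "hectare_years"  # or "hectares"
    exclude_positive_optima: bool = True

    def __post_init__(self):
        if self.window_length <= 0 or self.pre_sowing_windows <= 0 \
                or self.post_sowing_windows <= 0:
            raise ValueError("window counts/length must be positive")
        if not 0 < self.tree_alpha < 1:
            raise ValueError("tree_alpha must be in (0, 1)")
        if self.tree_min_terminal > self.tree_min_internal:
            raise ValueError("min_terminal must be ≤ min_internal")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if not 0 < self.boost_step <= 1:
            raise ValueError("boost step must be in (0, 1]")
        grid = sorted(self.shift_grid)
        if sorted(-s for s in grid) != grid:
            raise ValueError("shift grid must be symmetric around 0")
        self.shift_grid = tuple(grid)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"config: unknown key(s) {sorted(unknown)}")
        for key in ("shift_grid", "frost_thresholds"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["shift_grid"] = list(data["shift_grid"])
        data["frost_thresholds"] = list(data["frost_thresholds"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
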