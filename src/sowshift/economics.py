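"""Monetary effect of optimal sowing, in inflation-adjusted 2016 US$.

Three steps per state: (1) the percentage yield change at the optimal
shift is applied to each year's non-irrigated production; (2) each year's
total soybean income is deflated/inflated to 2016 purchasing power;
(3) the per-year products of income and fractional production change are
summed over the decade into a cumulative gain, and divided by the mean
cultivated hectares to give a per-hectare effect.  The per-hectare
denominator convention is configurable: mean hectares × number of years
(default; an annualized per-hectare rate is then the plain quotient) or
mean hectares alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError


def production_change(pct_yield_change: float, production_t: float) -> dict:
    """Fractional and absolute (tonnes) production change for one state-year."""
    if production_t < 0:
        raise ValidationError("production_change: negative production")
    frac = pct_yield_change / 100.0
    return {"fraction": frac, "tonnes": frac * production_t}


def inflation_adjust(income_usd: float, year: int, cpi: pd.DataFrame) -> float:
    """Income in 2016 US$: income × deflator_to_2016(year)."""
    row = cpi.loc[cpi["year"] == year, "deflator_to_2016"]
    if row.empty:
        raise ValidationError(f"inflation_adjust: no deflator for year {year}")
    return float(income_usd) * float(row.iloc[0])


def cumulative_gain(
    state: str,
    pct_yield_change: float,
    econ: pd.DataFrame,
    cpi: pd.DataFrame,
) -> dict:
    """Cumulative 2016-US$ gain for one state over its economics years."""
    sub = econ[econ["state"] == state]
    if sub.empty:
        raise ValidationError(f"cumulative_gain: no economics rows for {state}")
    per_year = []
    total = 0.0
    for _, row in sub.iterrows():
        change = production_change(pct_yield_change, row["production_t"])
        income16 = inflation_adjust(row["income_usd"], int(row["year"]), cpi)
        gain = income16 * change["fraction"]
        total += gain
        per_year.append({
            "year": int(row["year"]),
            "income_usd2016": income16,
            "change_fraction": change["fraction"],
            "change_tonnes": change["tonnes"],
            "gain_usd2016": gain,
        })
    return {"state": state, "cumulative_gain_usd2016": total, "per_year": per_year}


def per_hectare(gain_usd2016: float, mean_hectares: float, n_years: int,
                denominator: str = "hectare_years") -> float:
    """Per-hectare monetary effect under the chosen denominator convention."""
    if mean_hectares <= 0:
        raise ValidationError("per_hectare: zero or negative hectares")
    if denominator == "hectare_years":
        return gain_usd2016 / (mean_hectares * n_years)
    if denominator == "hectares":
        return gain_usd2016 / mean_hectares
    raise ValueError(f"unknown per-ha denominator {denominator!r}")


def economics_table(
    curves: pd.DataFrame,
    econ: pd.DataFrame,
    cpi: pd.DataFrame,
    denominator: str = "hectare_years",
) -> tuple[pd.DataFrame, dict]:
    """Per-state monetary results and the national roll-up.

    ``curves`` must carry ``state, gain_kg_ha, yield_at_zero_kg_ha`` (the
    fractional yield change at the optimum is their ratio).
    """
    rows = []
    for _, crow in curves.iterrows():
        state = crow["state"]
        pct = 100.0 * crow["gain_kg_ha"] / crow["yield_at_zero_kg_ha"]
        res = cumulative_gain(state, pct, econ, cpi)
        sub = econ[econ["state"] == state]
        mean_ha = float(sub["hectares"].mean())
        n_years = int(sub["year"].nunique())
        rows.append({
            "state": state,
            "pct_yield_change": pct,
            "cum_gain_usd2016": res["cumulative_gain_usd2016"],
            "per_ha_usd2016": per_hectare(
                res["cumulative_gain_usd2016"], mean_ha, n_years, denominator
            ),
        })
    table = pd.DataFrame(rows)
    national = {
        "cumulative_gain_usd2016": float(table["cum_gain_usd2016"].sum()),
        "n_states": int(len(table)),
        "per_ha_denominator": denominator,
    }
    return table, national
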