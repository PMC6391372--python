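"""Quadratic sowing-date response curves and state-specific optima.

Simulated scenario yields are fitted, per state, with a quadratic in the
sowing shift while year-to-year level differences (technology trend plus
the year's overall weather) are absorbed by year intercepts — a two-stage
reading of the hierarchical model in which year acts as a grouping level
and the shift response is the fixed quadratic of interest.  The optimum
shift is the vertex −b/(2c) of a concave fit, clipped to the simulated
−30..+30 grid; convex fits fall back to the best grid endpoint and are
flagged.  The yield gain is the fitted yield at the optimum minus at shift
zero, which is non-negative by construction for concave fits.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ValidationError


def _quadratic_fit_with_year_intercepts(sub: pd.DataFrame):
    """OLS of predicted yield on shift + shift² with per-year intercepts."""
    years = sorted(sub["year"].unique())
    s = sub["shift_days"].to_numpy(dtype=float)
    cols = [s, s ** 2]
    names = ["shift", "shift2"]
    for yr in years:
        cols.append((sub["year"] == yr).to_numpy(dtype=float))
        names.append(f"y{yr}")
    X = np.column_stack(cols)
    fit = sm.OLS(sub["pred_yield_kg_ha"].to_numpy(dtype=float), X).fit()
    return fit, names


def fit_response(
    scenarios: pd.DataFrame,
    shift_bounds: tuple[float, float] = (-30.0, 30.0),
) -> pd.DataFrame:
    """Per-state quadratic response curves from the scenario table.

    Returns one row per state: ``state, coeff_linear, coeff_quad,
    se_linear, se_quad, opt_shift_days, gain_kg_ha, yield_at_zero_kg_ha,
    convex_flag, clipped_flag, var_year``.
    """
    lo, hi = shift_bounds
    rows = []
    for state, sub in scenarios.groupby("state", sort=True):
        if sub["shift_days"].nunique() < 3:
            raise ValidationError(
                f"fit_response: state {state} has < 3 distinct shifts"
            )
        fit, names = _quadratic_fit_with_year_intercepts(sub)
        b = float(fit.params[0])
        c = float(fit.params[1])
        year_ints = fit.params[2:]
        convex = c >= 0
        clipped = False
        if convex:
            # no interior maximum: best shift on the simulated grid
            grid = np.array(sorted(sub["shift_days"].unique()), dtype=float)
            vals = b * grid + c * grid ** 2
            opt = float(grid[np.argmax(vals)])
        else:
            opt = -b / (2 * c)
            if opt < lo or opt > hi:
                clipped = True
                opt = float(np.clip(opt, lo, hi))
        gain = b * opt + c * opt ** 2
        yield0 = float(np.mean(year_ints))  # fitted yield at shift 0, mean year
        rows.append({
            "state": state,
            "coeff_linear": b,
            "coeff_quad": c,
            "se_linear": float(fit.bse[0]),
            "se_quad": float(fit.bse[1]),
            "opt_shift_days": opt,
            "gain_kg_ha": float(gain),
            "yield_at_zero_kg_ha": yield0,
            "convex_flag": bool(convex),
            "clipped_flag": bool(clipped),
            "var_year": float(np.var(year_ints, ddof=1)) if len(year_ints) > 1 else 0.0,
            "resid_sd": float(np.sqrt(fit.mse_resid)) if fit.df_resid > 0 else 0.0,
        })
    return pd.DataFrame(rows)


def national_summary(
    curves: pd.DataFrame,
    production_weights: dict[str, float],
    exclude_positive_optima: bool = True,
    weighted: bool = True,
) -> dict:
    """Production-weighted national mean optimal shift and total yield change.

    States with positive (later-than-typical) optima are excluded from the
    earlier-sowing headline by default; the exclusion and the weighting are
    configurable.  The total yield change is the weighted mean of per-state
    fractional gains at their optima, in percent.
    """
    missing = sorted(set(curves["state"]) - set(production_weights))
    if missing:
        raise ValidationError(f"national_summary: missing weight(s) for {missing}")
    sel = curves.copy()
    excluded = []
    if exclude_positive_optima:
        excluded = sorted(sel.loc[sel["opt_shift_days"] > 0, "state"])
        sel = sel[sel["opt_shift_days"] <= 0]
    if sel.empty:
        raise ValidationError("national_summary: no states after exclusion")
    w = np.array([production_weights[s] for s in sel["state"]], dtype=float)
    if not weighted:
        w = np.ones_like(w)
    opt = sel["opt_shift_days"].to_numpy(dtype=float)
    gain_frac = (
        sel["gain_kg_ha"].to_numpy(dtype=float)
        / sel["yield_at_zero_kg_ha"].to_numpy(dtype=float)
    )
    return {
        "mean_optimal_shift_days": float(np.sum(w * opt) / np.sum(w)),
        "total_yield_change_pct": float(100.0 * np.sum(w * gain_frac) / np.sum(w)),
        "excluded_states": excluded,
        "n_states": int(len(sel)),
    }
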