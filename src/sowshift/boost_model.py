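"""Predictive yield model: componentwise functional gradient descent (L2).

Boosting under squared-error loss: start from the training-mean offset,
then at every iteration fit one simple base learner per candidate feature
to the current residuals (the negative gradient), keep the learner with the
largest error reduction, and add ``step`` times that learner to the fit.
With step ≤ 1 the training MSE is non-increasing by construction.

Two base learners are offered: regression stumps (one threshold, two
levels — captures the threshold-like Vpd responses the tree stage finds)
and componentwise simple linear fits (whose boosting limit is the
ordinary-least-squares solution, a useful correctness anchor).

Evaluation follows a stratified train/test split — by default states are
sampled within years so both sets span the full decade — and reports
squared-Pearson R² and RMSE on the held-out rows.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class BoostControls:
    n_iter: int = 600
    step: float = 0.2
    base_learner: str = "componentwise_linear"  # or "stump"
    train_frac: float = 0.85
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.step <= 1:
            raise ValueError("step must be in (0, 1]")
        if self.n_iter < 0:
            raise ValueError("n_iter must be ≥ 0")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if self.base_learner not in ("stump", "componentwise_linear"):
            raise ValueError(f"unknown base learner {self.base_learner!r}")


@dataclasses.dataclass
class BoostModel:
    offset: float
    learners: list[dict]          # each: {feature, kind, ...params}, pre-scaled by step
    feature_names: list[str]
    controls: BoostControls
    train_mse_path: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------

def stratified_split(
    records: pd.DataFrame,
    train_frac: float = 0.85,
    strata: Sequence[str] = ("year",),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into train/test within strata.

    With the default ``strata=("year",)`` the states observed in each year
    are sampled so that ~``train_frac`` of them train the model — i.e.
    stratified by states within years.  Per stratum, the train count is
    ``round(n · train_frac)`` clipped so a stratum of ≥ 2 contributes at
    least one row to each side; singleton strata go to train (logged).
    """
    if len(records) < 2:
        raise ValidationError("stratified_split: need ≥ 2 records")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for _, group in records.groupby(list(strata), sort=True):
        idx = group.index.to_numpy()
        n = len(idx)
        if n == 1:
            logger.info("stratum of size 1 assigned to train")
            train_idx.extend(idx)
            continue
        n_train = int(round(n * train_frac))
        n_train = min(max(n_train, 1), n - 1)
        perm = rng.permutation(n)
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    return records.loc[sorted(train_idx)], records.loc[sorted(test_idx)]


# ---------------------------------------------------------------------------
# Base learners
# ---------------------------------------------------------------------------

def _fit_stump(xs: np.ndarray, order: np.ndarray, r: np.ndarray):
    """Best single-threshold stump for residuals ``r`` on presorted feature.

    Returns (sse_reduction, params) or None if the feature is constant.
    xs = x[order] (sorted values).
    """
    n = len(r)
    rs = r[order]
    csum = np.cumsum(rs)
    total = csum[-1]
    i = np.arange(1, n)
    valid = xs[:-1] != xs[1:]
    if not valid.any():
        return None
    s_l = csum[:-1]
    s_r = total - s_l
    red = s_l**2 / i + s_r**2 / (n - i) - total**2 / n
    red = np.where(valid, red, -np.inf)
    k = int(np.argmax(red))
    threshold = 0.5 * (xs[k] + xs[k + 1])
    n_l = k + 1
    left_val = s_l[k] / n_l
    right_val = s_r[k] / (n - n_l)
    return float(red[k]), {"threshold": float(threshold),
                           "left": float(left_val), "right": float(right_val)}


def _fit_linear(x: np.ndarray, sxx: float, r: np.ndarray):
    """Simple OLS of residuals on one centered feature (intercept + slope)."""
    if sxx == 0:
        return None
    rc = r - r.mean()
    slope = float(np.dot(x, rc) / sxx)  # x pre-centered
    intercept = float(r.mean())
    red = slope * np.dot(x, rc) + len(r) * intercept**2
    return float(red), {"intercept": intercept, "slope": slope}


def fit_boost(
    X: pd.DataFrame, y, controls: Optional[BoostControls] = None,
) -> BoostModel:
    """Fit the boosting model on a numeric feature frame.

    Missing values are rejected; the model references only the supplied
    feature schema.  ``n_iter = 0`` returns the offset-only model.
    """
    controls = controls or BoostControls()
    Xv = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if Xv.shape[0] != len(y):
        raise ValidationError("fit_boost: X and y length mismatch")
    if not np.all(np.isfinite(Xv)):
        raise ValidationError("fit_boost: missing/non-finite feature values")
    n, m = Xv.shape
    offset = float(y.mean())
    fit = np.full(n, offset)
    learners: list[dict] = []
    mse_path = np.empty(controls.n_iter + 1)
    mse_path[0] = float(np.mean((y - fit) ** 2))

    if controls.base_learner == "stump":
        orders = [np.argsort(Xv[:, j], kind="stable") for j in range(m)]
        sorted_x = [Xv[orders[j], j] for j in range(m)]
    else:
        means = Xv.mean(axis=0)
        Xc = Xv - means
        sxx = (Xc ** 2).sum(axis=0)

    nu = controls.step
    for it in range(controls.n_iter):
        r = y - fit
        best = None
        for j in range(m):
            if controls.base_learner == "stump":
                res = _fit_stump(sorted_x[j], orders[j], r)
            else:
                res = _fit_linear(Xc[:, j], sxx[j], r)
            if res is None:
                continue
            red, params = res
            if best is None or red > best[0]:
                best = (red, j, params)
        if best is None:
            mse_path[it + 1:] = mse_path[it]
            break
        _, j, params = best
        if controls.base_learner == "stump":
            contrib = np.where(Xv[:, j] <= params["threshold"],
                               params["left"], params["right"])
            learners.append({
                "feature": X.columns[j], "kind": "stump",
                "threshold": params["threshold"],
                "left": nu * params["left"], "right": nu * params["right"],
            })
        else:
            contrib = params["intercept"] + params["slope"] * Xc[:, j]
            learners.append({
                "feature": X.columns[j], "kind": "linear",
                "center": float(means[j]),
                "intercept": nu * params["intercept"],
                "slope": nu * params["slope"],
            })
        fit = fit + nu * contrib
        mse_path[it + 1] = float(np.mean((y - fit) ** 2))

    return BoostModel(offset=offset, learners=learners,
                      feature_names=list(X.columns), controls=controls,
                      train_mse_path=mse_path)


def predict_boost(model: BoostModel, X: pd.DataFrame) -> np.ndarray:
    """Deterministic predictions: offset + Σ scaled base-learner evaluations."""
    missing = [f for f in model.feature_names if f not in X.columns]
    if missing:
        raise ValidationError(f"predict_boost: missing feature(s) {missing}")
    out = np.full(len(X), model.offset)
    cols = {f: X[f].to_numpy(dtype=float) for f in model.feature_names}
    for lrn in model.learners:
        xv = cols[lrn["feature"]]
        if lrn["kind"] == "stump":
            out = out + np.where(xv <= lrn["threshold"], lrn["left"], lrn["right"])
        else:
            out = out + lrn["intercept"] + lrn["slope"] * (xv - lrn["center"])
    return out


def evaluate(model: BoostModel, X: pd.DataFrame, y) -> dict:
    """Held-out fit quality: squared-Pearson R² and RMSE."""
    y = np.asarray(y, dtype=float)
    pred = predict_boost(model, X)
    rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
    if np.std(pred) == 0 or np.std(y) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(pred, y)[0, 1] ** 2)
    return {"r2": r2, "rmse": rmse}


def model_to_json(model: BoostModel, path=None) -> str:
    doc = json.dumps({
        "offset": model.offset,
        "feature_names": model.feature_names,
        "controls": dataclasses.asdict(model.controls),
        "learners": model.learners,
    }, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(doc)
    return doc


def model_from_json(doc: str) -> BoostModel:
    raw = json.loads(doc)
    return BoostModel(offset=raw["offset"], learners=raw["learners"],
                      feature_names=raw["feature_names"],
                      controls=BoostControls(**raw["controls"]))
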