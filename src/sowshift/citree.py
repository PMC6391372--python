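"""Conditional-inference regression tree for yield partitioning.

Binary recursive partitioning in a conditional-inference framework: at each
node the global null of independence between yield and every candidate
predictor is tested with permutation p-values (Bonferroni-adjusted across
predictors); if it cannot be rejected the node stops, otherwise the most
strongly associated predictor is split at the cut point maximizing the
standardized two-sample mean contrast.  Stopping is therefore statistical,
not impurity-based, which avoids the variable-selection bias of classic
CART and gives interpretable, pre-specified significance control.

The association test uses a Monte-Carlo permutation distribution of a
linear statistic: the centered cross-product for numeric predictors and a
group-sum quadratic form for the categorical state variable.  All
predictors at a node share one set of response permutations.

Within-node slope regressions (yield on a chosen window feature, with a
state × feature interaction F-test for slope homogeneity) quantify the
per-kPa yield loss inside tree-defined strata.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ValidationError

SplitPoint = Union[float, tuple]  # numeric threshold, or categories routed left


@dataclasses.dataclass
class CITreeControls:
    """Stopping and testing controls for tree growth.

    Defaults mirror an interpretation-first analysis of ~186 observations:
    splits require > 37 observations, leaves > 18, Bonferroni-adjusted
    permutation tests at alpha = 0.05, depth capped at 10.
    """

    alpha: float = 0.05
    bonferroni: bool = True
    min_internal: int = 38
    min_terminal: int = 19
    max_depth: int = 10
    n_perm: int = 9999
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_terminal > self.min_internal:
            raise ValueError("min_terminal must be ≤ min_internal")
        if self.max_depth < 1:
            raise ValueError("max_depth must be ≥ 1")


@dataclasses.dataclass
class CITreeNode:
    node_id: int
    n: int
    mean_yield: float
    split_variable: Optional[str] = None
    split_point: Optional[SplitPoint] = None
    p_value: Optional[float] = None
    left: Optional["CITreeNode"] = None
    right: Optional["CITreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.split_variable is None


@dataclasses.dataclass
class CITree:
    root: CITreeNode
    feature_names: list[str]
    controls: CITreeControls
    n_obs: int


# ---------------------------------------------------------------------------
# Permutation association tests
# ---------------------------------------------------------------------------

def _permuted_responses(y: np.ndarray, n_perm: int, rng: np.random.Generator):
    """(n_perm, n) matrix of permuted centered responses."""
    yc = y - y.mean()
    tiled = np.tile(yc, (n_perm, 1))
    return rng.permuted(tiled, axis=1)


def _numeric_stats(xc: np.ndarray, Yc: np.ndarray) -> np.ndarray:
    """|Σ (x−x̄)(y−ȳ)| for each permuted response row."""
    return np.abs(Yc @ xc)


def _categorical_stats(codes: np.ndarray, counts: np.ndarray,
                       Yc: np.ndarray) -> np.ndarray:
    """Between-group quadratic form Σ_g S_g²/n_g for each permuted row."""
    k = len(counts)
    n_perm, n = Yc.shape
    sums = np.zeros((n_perm, k))
    for g in range(k):
        sums[:, g] = Yc[:, codes == g].sum(axis=1)
    return (sums ** 2 / counts).sum(axis=1)


def _column_test(x: pd.Series, y: np.ndarray,
                 Yc_perm: np.ndarray) -> tuple[float, float]:
    """Monte-Carlo permutation test for one predictor column.

    ``Yc_perm``'s first row must be the observed (unpermuted) centered
    response.  Returns ``(p, z)`` where p = (1 + #{perm stat ≥ observed})
    / (1 + n_perm) and z is the observed statistic standardized by the
    permutation distribution (used only to break ties among p-values that
    saturate at the Monte-Carlo resolution floor).
    """
    if np.ptp(y) == 0:
        return 1.0, 0.0
    if x.dtype == object or isinstance(x.dtype, pd.CategoricalDtype):
        codes, _ = pd.factorize(x, sort=True)
        counts = np.bincount(codes).astype(float)
        if len(counts) < 2:
            return 1.0, 0.0
        stats = _categorical_stats(codes, counts, Yc_perm)
    else:
        xv = x.to_numpy(dtype=float)
        if np.ptp(xv) == 0:
            return 1.0, 0.0
        xc = xv - xv.mean()
        stats = _numeric_stats(xc, Yc_perm)
    obs = stats[0]
    perm = stats[1:]
    tol = 1e-12 * max(obs, 1.0)
    p = float((1 + np.sum(perm >= obs - tol)) / (1 + len(perm)))
    sd = float(perm.std())
    z = float((obs - perm.mean()) / sd) if sd > 0 else 0.0
    return p, z


def association_pvalue(x, y, n_perm: int = 9999, seed: int = 0) -> float:
    """Permutation p-value for association between one predictor and yield.

    Numeric predictors use the absolute centered cross-product statistic;
    categorical predictors a between-group quadratic form.  Constant ``x``
    or ``y`` returns 1 by convention.
    """
    x = pd.Series(x)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("association_pvalue: length mismatch")
    if len(y) < 3:
        raise ValidationError("association_pvalue: need ≥ 3 observations")
    rng = np.random.default_rng(seed)
    Yc = np.vstack([y - y.mean(), _permuted_responses(y, n_perm, rng)])
    return _column_test(x, y, Yc)[0]


def select_split_variable(
    X: pd.DataFrame, y: np.ndarray, controls: CITreeControls,
    rng: np.random.Generator,
) -> Optional[tuple[str, float]]:
    """Most associated predictor with its Bonferroni-adjusted p, or None.

    All predictors share one permutation set.  Returns None when even the
    smallest adjusted p exceeds alpha (the global independence null stands).
    Ties break to the first column in ``X``'s order.
    """
    Yc = np.vstack([y - y.mean(),
                    _permuted_responses(y, controls.n_perm, rng)])
    m = X.shape[1]
    best = None  # (p_adj, -z, column index, name)
    for i, name in enumerate(X.columns):
        p, z = _column_test(X[name], y, Yc)
        if controls.bonferroni:
            p = min(1.0, p * m)
        key = (p, -z, i)
        if best is None or key < best[:3]:
            best = (p, -z, i, name)
    if best is None or best[0] > controls.alpha:
        return None
    return best[3], float(best[0])


# ---------------------------------------------------------------------------
# Split search
# ---------------------------------------------------------------------------

def _best_ordered_cut(order: np.ndarray, xv: np.ndarray, y: np.ndarray,
                      min_terminal: int) -> Optional[tuple[int, float]]:
    """Best cut index along a given observation ordering.

    Returns ``(i, stat)`` meaning the first ``i`` ordered observations go
    left, maximizing the standardized two-sample mean-difference statistic,
    or None if no admissible cut exists.  Cuts are only allowed between
    distinct predictor values.
    """
    n = len(y)
    ys = y[order]
    xs = xv[order]
    csum = np.cumsum(ys)
    total = csum[-1]
    i_arr = np.arange(1, n)  # left-side counts
    s_y = np.std(y, ddof=1) if n > 1 else 0.0
    if s_y == 0:
        return None
    # standardized statistic |S_i − i·ȳ| / (s_y · sqrt(i(n−i)/n))
    num = np.abs(csum[:-1] - i_arr * (total / n))
    den = s_y * np.sqrt(i_arr * (n - i_arr) / n)
    stat = num / den
    ok = (i_arr >= min_terminal) & ((n - i_arr) >= min_terminal)
    ok &= xs[:-1] != xs[1:]  # no cut inside a run of equal values
    if not ok.any():
        return None
    stat = np.where(ok, stat, -np.inf)
    i_best = int(np.argmax(stat))  # ties → smallest cut index
    return i_best + 1, float(stat[i_best])


def best_binary_split(
    x, y, min_terminal: int,
) -> Optional[tuple[SplitPoint, np.ndarray]]:
    """Best admissible binary split of the selected variable.

    Numeric variables: threshold at the midpoint of the adjacent observed
    values around the maximizing cut; the left child takes ``x ≤ threshold``.
    Categorical variables: categories are ordered by mean response and the
    cut searched along that ordering (exact for least-squares criteria);
    the left child takes the returned category tuple.

    Returns ``(split_point, left_mask)`` or None when no cut leaves
    ``min_terminal`` observations on both sides.
    """
    x = pd.Series(x).reset_index(drop=True)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if x.dtype == object or isinstance(x.dtype, pd.CategoricalDtype):
        codes, uniques = pd.factorize(x, sort=True)
        means = np.array([y[codes == g].mean() for g in range(len(uniques))])
        cat_order = np.argsort(means, kind="stable")
        rank = np.empty(len(uniques), dtype=int)
        rank[cat_order] = np.arange(len(uniques))
        ordered_vals = rank[codes].astype(float)
        order = np.argsort(ordered_vals, kind="stable")
        res = _best_ordered_cut(order, ordered_vals, y, min_terminal)
        if res is None:
            return None
        i, _ = res
        left_ranks = set(ordered_vals[order][:i].astype(int))
        left_cats = tuple(sorted(str(uniques[g]) for g in range(len(uniques))
                                 if rank[g] in left_ranks))
        left_mask = np.isin(x.astype(str).to_numpy(), left_cats)
        return left_cats, left_mask
    xv = x.to_numpy(dtype=float)
    order = np.argsort(xv, kind="stable")
    res = _best_ordered_cut(order, xv, y, min_terminal)
    if res is None:
        return None
    i, _ = res
    xs = xv[order]
    threshold = 0.5 * (xs[i - 1] + xs[i])
    return float(threshold), xv <= threshold


# ---------------------------------------------------------------------------
# Tree growth and prediction
# ---------------------------------------------------------------------------

def fit_citree(X: pd.DataFrame, y, controls: Optional[CITreeControls] = None) -> CITree:
    """Grow a conditional-inference regression tree.

    ``X`` is the predictor frame (numeric window features plus an optional
    categorical ``state`` column); ``y`` the yield vector.
    """
    controls = controls or CITreeControls()
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValidationError("fit_citree: X and y length mismatch")
    rng = np.random.default_rng(controls.seed)
    counter = [0]

    def _grow(idx: np.ndarray, depth: int) -> CITreeNode:
        node = CITreeNode(node_id=counter[0], n=len(idx),
                          mean_yield=float(y[idx].mean()))
        counter[0] += 1
        if len(idx) < controls.min_internal or depth >= controls.max_depth:
            return node
        sub_X = X.iloc[idx].reset_index(drop=True)
        sel = select_split_variable(sub_X, y[idx], controls, rng)
        if sel is None:
            return node
        var, p_adj = sel
        split = best_binary_split(sub_X[var], y[idx], controls.min_terminal)
        if split is None:
            return node
        point, left_mask = split
        node.split_variable = var
        node.split_point = point
        node.p_value = p_adj
        node.left = _grow(idx[left_mask], depth + 1)
        node.right = _grow(idx[~left_mask], depth + 1)
        return node

    root = _grow(np.arange(len(y)), 0)
    return CITree(root=root, feature_names=list(X.columns),
                  controls=controls, n_obs=len(y))


def _route(node: CITreeNode, row: pd.Series) -> CITreeNode:
    while not node.is_leaf:
        if isinstance(node.split_point, tuple):
            go_left = str(row[node.split_variable]) in node.split_point
        else:
            go_left = float(row[node.split_variable]) <= node.split_point
        node = node.left if go_left else node.right
    return node


def predict_citree(tree: CITree, X: pd.DataFrame) -> np.ndarray:
    """Mean yield of the leaf each row routes to."""
    return np.array([_route(tree.root, row).mean_yield for _, row in X.iterrows()])


def leaf_assignments(tree: CITree, X: pd.DataFrame) -> np.ndarray:
    """Leaf node_id each row routes to (defines the tree's strata)."""
    return np.array([_route(tree.root, row).node_id for _, row in X.iterrows()])


def iter_nodes(tree: CITree):
    stack = [tree.root]
    while stack:
        node = stack.pop()
        yield node
        if not node.is_leaf:
            stack.extend([node.right, node.left])


# ---------------------------------------------------------------------------
# Within-stratum slope regression
# ---------------------------------------------------------------------------

def node_vpd_slope(subset: pd.DataFrame, predictor: str,
                   response: str = "yield_kg_ha") -> dict:
    """OLS slope of yield on a window feature within a tree stratum.

    Returns slope (kg/ha per predictor unit), its 95% CI and standard
    error, and — when more than one state is present — the p-value of the
    state × predictor interaction F-test (slope homogeneity across states).
    """
    if len(subset) < 3:
        raise ValidationError("node_vpd_slope: need ≥ 3 observations")
    xv = subset[predictor].to_numpy(dtype=float)
    if np.ptp(xv) == 0:
        raise ValidationError(f"node_vpd_slope: constant predictor {predictor}")
    X = sm.add_constant(xv)
    fit = sm.OLS(subset[response].to_numpy(dtype=float), X).fit()
    ci = fit.conf_int(alpha=0.05)
    out = {
        "slope": float(fit.params[1]),
        "stderr": float(fit.bse[1]),
        "ci_low": float(ci[1][0]),
        "ci_high": float(ci[1][1]),
        "n": int(len(subset)),
        "homogeneity_p": None,
    }
    if "state" in subset.columns and subset["state"].nunique() > 1:
        d = subset.rename(columns={predictor: "_x", response: "_y"})
        # need ≥2 obs per state for the interaction fit to be meaningful
        base = smf.ols("_y ~ C(state) + _x", data=d).fit()
        inter = smf.ols("_y ~ C(state) * _x", data=d).fit()
        if inter.df_resid > 0:
            ftest = inter.compare_f_test(base)
            out["homogeneity_p"] = float(ftest[1])
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _node_to_dict(node: CITreeNode) -> dict:
    d = {
        "node_id": node.node_id,
        "n": node.n,
        "mean_yield": node.mean_yield,
    }
    if not node.is_leaf:
        d.update({
            "split_variable": node.split_variable,
            "split_point": list(node.split_point)
            if isinstance(node.split_point, tuple) else node.split_point,
            "p_value": node.p_value,
            "left": _node_to_dict(node.left),
            "right": _node_to_dict(node.right),
        })
    return d


def tree_to_json(tree: CITree, path=None) -> str:
    doc = json.dumps({
        "n_obs": tree.n_obs,
        "feature_names": tree.feature_names,
        "controls": dataclasses.asdict(tree.controls),
        "root": _node_to_dict(tree.root),
    }, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(doc)
    return doc


def render_text(tree: CITree) -> str:
    """Plain-text indented rendering of the fitted tree."""
    lines: list[str] = []

    def _walk(node: CITreeNode, indent: int, prefix: str) -> None:
        pad = "  " * indent
        if node.is_leaf:
            lines.append(f"{pad}{prefix}leaf [{node.node_id}] "
                         f"n={node.n} mean={node.mean_yield:.0f}")
            return
        if isinstance(node.split_point, tuple):
            cond = f"{node.split_variable} in {{{', '.join(node.split_point)}}}"
        else:
            cond = f"{node.split_variable} <= {node.split_point:.3g}"
        lines.append(f"{pad}{prefix}[{node.node_id}] {cond} "
                     f"(p={node.p_value:.4g}, n={node.n})")
        _walk(node.left, indent + 1, "yes: ")
        _walk(node.right, indent + 1, "no:  ")

    _walk(tree.root, 0, "")
    return "\n".join(lines)
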