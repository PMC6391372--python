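"""Conditional-inference tree: permutation tests, splits, growth, slopes."""

import numpy as np
import pandas as pd
import pytest

from sowshift import citree
from sowshift.errors import ValidationError


def exhaustive_best_cut(x, y, min_terminal):
    """Brute-force oracle: scan every admissible threshold."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    s_y = np.std(y, ddof=1)
    xs = np.unique(x)
    best = None
    for lo, hi in zip(xs[:-1], xs[1:]):
        thr = 0.5 * (lo + hi)
        left = x <= thr
        n_l = int(left.sum())
        if n_l < min_terminal or n - n_l < min_terminal:
            continue
        stat = abs(y[left].sum() - n_l * y.mean()) / (
            s_y * np.sqrt(n_l * (n - n_l) / n)
        )
        if best is None or stat > best[0] + 1e-12:
            best = (stat, thr)
    return None if best is None else best[1]


class TestAssociationPvalue:
    def test_strong_linear_signal(self):
        r = np.random.default_rng(0)
        x = r.normal(size=40)
        y = 2 * x + r.normal(scale=1e-3, size=40)
        assert citree.association_pvalue(x, y, n_perm=4999, seed=1) <= 0.001

    def test_constant_response_convention(self):
        x = np.arange(10.0)
        assert citree.association_pvalue(x, np.ones(10)) == 1.0
        assert citree.association_pvalue(np.ones(10), np.arange(10.0)) == 1.0

    def test_reproducible_given_seed(self):
        r = np.random.default_rng(2)
        x, y = r.normal(size=30), r.normal(size=30)
        p1 = citree.association_pvalue(x, y, n_perm=999, seed=7)
        p2 = citree.association_pvalue(x, y, n_perm=999, seed=7)
        assert p1 == p2

    def test_categorical_group_contrast(self):
        r = np.random.default_rng(3)
        x = pd.Series(["a"] * 20 + ["b"] * 20)
        y = np.r_[r.normal(0, 1, 20), r.normal(4, 1, 20)]
        assert citree.association_pvalue(x, y, n_perm=1999, seed=0) < 0.01

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            citree.association_pvalue([1, 2, 3], [1, 2])


class TestSelectSplitVariable:
    def test_planted_signal_found(self):
        controls = citree.CITreeControls(n_perm=999, seed=0)
        found = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            X = pd.DataFrame(r.normal(size=(60, 10)),
                             columns=[f"v{j}" for j in range(10)])
            y = 3 * X["v4"].to_numpy() + r.normal(scale=0.5, size=60)
            sel = citree.select_split_variable(
                X, y, controls, np.random.default_rng(rep)
            )
            if sel is not None and sel[0] == "v4":
                found += 1
        assert found >= 19

    def test_null_stops_mostly(self):
        controls = citree.CITreeControls(n_perm=499, seed=0)
        stops = 0
        n_rep = 60
        for rep in range(n_rep):
            r = np.random.default_rng(1000 + rep)
            X = pd.DataFrame(r.normal(size=(50, 10)),
                             columns=[f"v{j}" for j in range(10)])
            y = r.normal(size=50)
            if citree.select_split_variable(
                X, y, controls, np.random.default_rng(rep)
            ) is None:
                stops += 1
        # Bonferroni keeps the familywise rate ≤ alpha: expect ≥ ~95% stops
        assert stops / n_rep >= 0.85

    def test_identical_columns_tie_break_by_order(self):
        r = np.random.default_rng(5)
        x = r.normal(size=50)
        X = pd.DataFrame({"a": x, "b": x})
        y = 2 * x + r.normal(scale=0.1, size=50)
        controls = citree.CITreeControls(n_perm=999, seed=0)
        sel = citree.select_split_variable(X, y, controls,
                                           np.random.default_rng(0))
        assert sel[0] == "a"


class TestBestBinarySplit:
    def test_step_function_threshold(self):
        x = np.repeat(np.arange(1, 11), 4).astype(float)
        y = np.where(x <= 5, 1.0, 5.0)
        point, mask = citree.best_binary_split(x, y, min_terminal=4)
        assert point == pytest.approx(5.5)
        assert mask.sum() == 20

    def test_matches_exhaustive_oracle(self):
        for rep in range(25):
            r = np.random.default_rng(rep)
            x = r.normal(size=40)
            y = r.normal(size=40) + (x > r.normal()) * r.uniform(0, 3)
            res = citree.best_binary_split(x, y, min_terminal=5)
            oracle = exhaustive_best_cut(x, y, min_terminal=5)
            if oracle is None:
                assert res is None
            else:
                assert res[0] == pytest.approx(oracle)

    def test_constant_response_is_leaf(self):
        assert citree.best_binary_split(np.arange(20.0), np.ones(20), 5) is None

    def test_no_admissible_cut(self):
        assert citree.best_binary_split(np.ones(20), np.arange(20.0), 5) is None

    def test_categorical_split_orders_by_mean(self):
        y = np.r_[np.full(10, 1.0), np.full(10, 5.0), np.full(10, 9.0)]
        x = pd.Series(["m"] * 10 + ["h"] * 10 + ["l"] * 10)
        point, mask = citree.best_binary_split(x, y, min_terminal=5)
        assert isinstance(point, tuple)
        assert set(point) in ({"m"}, {"m", "h"})  # lowest-mean side


class TestFitAndPredict:
    @pytest.fixture()
    def planted(self):
        r = np.random.default_rng(10)
        n = 200
        X = pd.DataFrame({
            "signal": r.uniform(0, 10, n),
            "noise1": r.normal(size=n),
            "noise2": r.normal(size=n),
            "state": pd.Series(r.choice(["A", "B", "C"], n)),
        })
        y = np.where(X["signal"] > 5, 4000.0, 3000.0) + r.normal(0, 100, n)
        return X, y

    def test_structure_and_controls(self, planted):
        X, y = planted
        controls = citree.CITreeControls(min_internal=38, min_terminal=19,
                                         max_depth=3, n_perm=999, seed=0)
        tree = citree.fit_citree(X, y, controls)
        assert tree.root.split_variable == "signal"
        depths, sizes = [], []

        def _walk(node, d):
            if node.is_leaf:
                depths.append(d)
                sizes.append(node.n)
            else:
                assert node.n >= controls.min_internal
                _walk(node.left, d + 1)
                _walk(node.right, d + 1)

        _walk(tree.root, 0)
        assert max(depths) <= controls.max_depth
        assert min(sizes) >= controls.min_terminal

    def test_leaf_means_conserve_grand_mean(self, planted):
        X, y = planted
        tree = citree.fit_citree(
            X, y, citree.CITreeControls(n_perm=499, seed=0)
        )
        total = 0.0
        for node in citree.iter_nodes(tree):
            if node.is_leaf:
                total += node.n * node.mean_yield
        assert total / len(y) == pytest.approx(y.mean())

    def test_pure_noise_single_leaf(self):
        r = np.random.default_rng(11)
        X = pd.DataFrame(r.normal(size=(100, 5)),
                         columns=[f"v{j}" for j in range(5)])
        y = r.normal(size=100)
        tree = citree.fit_citree(X, y, citree.CITreeControls(n_perm=999, seed=0))
        assert tree.root.is_leaf
        assert citree.predict_citree(tree, X.head(3)) == pytest.approx(
            [y.mean()] * 3
        )

    def test_too_few_observations_single_leaf(self):
        X = pd.DataFrame({"v": np.arange(10.0)})
        y = np.arange(10.0)
        tree = citree.fit_citree(X, y, citree.CITreeControls(n_perm=99, seed=0))
        assert tree.root.is_leaf

    def test_sensitivity_to_relaxed_minimums(self, planted):
        """Allowing smaller nodes must not change the dominant split."""
        X, y = planted
        strict = citree.fit_citree(
            X, y, citree.CITreeControls(min_internal=38, min_terminal=19,
                                        n_perm=999, seed=0)
        )
        relaxed = citree.fit_citree(
            X, y, citree.CITreeControls(min_internal=10, min_terminal=5,
                                        n_perm=999, seed=0)
        )
        assert strict.root.split_variable == relaxed.root.split_variable
        assert strict.root.split_point == pytest.approx(
            relaxed.root.split_point, abs=0.5
        )

    def test_json_roundtrip_and_render(self, planted):
        X, y = planted
        tree = citree.fit_citree(X, y, citree.CITreeControls(n_perm=499, seed=0))
        doc = citree.tree_to_json(tree)
        assert '"split_variable": "signal"' in doc
        text = citree.render_text(tree)
        assert "signal <=" in text


class TestNodeVpdSlope:
    def test_two_points_exact_line(self):
        sub = pd.DataFrame({"vpd_mean_W3": [1.0, 2.0, 3.0],
                            "yield_kg_ha": [4000.0, 3000.0, 2000.0]})
        res = citree.node_vpd_slope(sub, "vpd_mean_W3")
        assert res["slope"] == pytest.approx(-1000.0)

    def test_planted_slope_recovery(self):
        r = np.random.default_rng(12)
        vpd = r.uniform(1, 3, 100)
        sub = pd.DataFrame({
            "vpd_mean_W3": vpd,
            "yield_kg_ha": 5000.0 - 1135.0 * vpd + r.normal(0, 150, 100),
            "state": r.choice(["IA", "IL", "MN"], 100),
        })
        res = citree.node_vpd_slope(sub, "vpd_mean_W3")
        assert res["ci_low"] < -1135.0 < res["ci_high"]
        assert res["homogeneity_p"] > 0.05  # common slope planted

    def test_null_slope_ci_covers_zero(self):
        covered = 0
        for rep in range(40):
            r = np.random.default_rng(rep)
            sub = pd.DataFrame({
                "vpd_mean_W3": r.uniform(1, 3, 50),
                "yield_kg_ha": r.normal(3000, 200, 50),
            })
            res = citree.node_vpd_slope(sub, "vpd_mean_W3")
            if res["ci_low"] <= 0.0 <= res["ci_high"]:
                covered += 1
        assert covered >= 33  # ≈95% nominal coverage

    def test_constant_predictor_rejected(self):
        sub = pd.DataFrame({"vpd_mean_W3": [2.0] * 5,
                            "yield_kg_ha": [1.0, 2, 3, 4, 5.0]})
        with pytest.raises(ValidationError, match="constant"):
            citree.node_vpd_slope(sub, "vpd_mean_W3")
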