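"""Componentwise L2 boosting: split, fit, predict, evaluate."""

import numpy as np
import pandas as pd
import pytest

from sowshift import boost_model as bm
from sowshift.errors import ValidationError


def _records(n_years=3, per_year=20, seed=0):
    r = np.random.default_rng(seed)
    rows = []
    for y in range(2007, 2007 + n_years):
        for k in range(per_year):
            rows.append({"year": y, "x": r.normal(), "yield": r.normal()})
    return pd.DataFrame(rows)


class TestStratifiedSplit:
    def test_rounding_rule(self):
        recs = _records(1, 20)
        train, test = bm.stratified_split(recs, 0.85, ("year",), seed=0)
        assert len(train) == 17 and len(test) == 3

    def test_deterministic_and_seed_sensitive(self):
        recs = _records(3, 20)
        t1, _ = bm.stratified_split(recs, 0.85, ("year",), seed=1)
        t2, _ = bm.stratified_split(recs, 0.85, ("year",), seed=1)
        t3, _ = bm.stratified_split(recs, 0.85, ("year",), seed=2)
        assert t1.index.tolist() == t2.index.tolist()
        assert t1.index.tolist() != t3.index.tolist()

    def test_disjoint_exhaustive(self):
        recs = _records(4, 13)
        train, test = bm.stratified_split(recs, 0.85, ("year",), seed=3)
        assert set(train.index).isdisjoint(test.index)
        assert set(train.index) | set(test.index) == set(recs.index)

    def test_singleton_stratum_goes_to_train(self):
        recs = _records(1, 1)
        recs = pd.concat([recs, _records(1, 4, 1).assign(year=2008)],
                         ignore_index=True)
        train, test = bm.stratified_split(recs, 0.85, ("year",), seed=0)
        assert (train["year"] == 2007).sum() == 1
        assert (test["year"] == 2007).sum() == 0


def _linear_problem(n=120, seed=0):
    r = np.random.default_rng(seed)
    X = pd.DataFrame({"x": r.uniform(-2, 2, n)})
    y = 3.0 + 1.7 * X["x"].to_numpy() + r.normal(0, 0.3, n)
    return X, y


class TestFitBoost:
    def test_zero_iterations_offset_only(self):
        X, y = _linear_problem()
        model = bm.fit_boost(X, y, bm.BoostControls(n_iter=0))
        assert model.learners == []
        assert bm.predict_boost(model, X) == pytest.approx(
            np.full(len(y), y.mean())
        )

    def test_componentwise_linear_converges_to_ols(self):
        X, y = _linear_problem()
        model = bm.fit_boost(
            X, y, bm.BoostControls(n_iter=600, step=0.2,
                                   base_learner="componentwise_linear")
        )
        coeffs = np.polyfit(X["x"], y, 1)
        ols_pred = coeffs[1] + coeffs[0] * X["x"].to_numpy()
        pred = bm.predict_boost(model, X)
        rel = np.abs(pred - ols_pred) / np.abs(ols_pred).mean()
        assert rel.max() < 0.01

    @pytest.mark.parametrize("learner", ["stump", "componentwise_linear"])
    def test_training_mse_monotone_nonincreasing(self, learner):
        r = np.random.default_rng(4)
        X = pd.DataFrame(r.normal(size=(80, 5)),
                         columns=[f"v{j}" for j in range(5)])
        y = X["v0"] * 2 - (X["v1"] > 0) + r.normal(0, 0.5, 80)
        model = bm.fit_boost(
            X, y, bm.BoostControls(n_iter=200, base_learner=learner)
        )
        assert np.all(np.diff(model.train_mse_path) <= 1e-12)

    def test_step_halving_stability(self):
        """Half the step with double the iterations ≈ same converged fit."""
        X, y = _linear_problem()
        m1 = bm.fit_boost(X, y, bm.BoostControls(n_iter=600, step=0.2,
                                                 base_learner="componentwise_linear"))
        m2 = bm.fit_boost(X, y, bm.BoostControls(n_iter=1200, step=0.1,
                                                 base_learner="componentwise_linear"))
        p1, p2 = bm.predict_boost(m1, X), bm.predict_boost(m2, X)
        assert np.abs(p1 - p2).max() / np.abs(p1).mean() < 0.01

    def test_missing_values_rejected(self):
        X, y = _linear_problem(20)
        X.loc[3, "x"] = np.nan
        with pytest.raises(ValidationError):
            bm.fit_boost(X, y)

    def test_stump_fits_threshold_truth(self):
        r = np.random.default_rng(6)
        X = pd.DataFrame({"x": r.uniform(0, 10, 150), "junk": r.normal(size=150)})
        y = np.where(X["x"] > 6.0, 10.0, 2.0) + r.normal(0, 0.2, 150)
        model = bm.fit_boost(
            X, y, bm.BoostControls(n_iter=150, base_learner="stump")
        )
        pred = bm.predict_boost(model, X)
        assert np.corrcoef(pred, y)[0, 1] ** 2 > 0.95


class TestEvaluate:
    def test_rmse_of_offset_model_is_response_sd(self):
        X, y = _linear_problem(200, seed=9)
        model = bm.fit_boost(X, y, bm.BoostControls(n_iter=0))
        ev = bm.evaluate(model, X, y)
        assert ev["rmse"] == pytest.approx(np.std(y), rel=1e-9)
        assert ev["r2"] == 0.0  # constant prediction

    def test_null_features_r2_near_zero(self):
        r = np.random.default_rng(10)
        X_tr = pd.DataFrame(r.normal(size=(150, 4)),
                            columns=[f"v{j}" for j in range(4)])
        y_tr = r.normal(size=150)
        X_te = pd.DataFrame(r.normal(size=(150, 4)), columns=X_tr.columns)
        y_te = r.normal(size=150)
        model = bm.fit_boost(X_tr, y_tr, bm.BoostControls(
            n_iter=100, base_learner="componentwise_linear"))
        assert bm.evaluate(model, X_te, y_te)["r2"] < 0.1

    def test_schema_mismatch_lists_missing(self):
        X, y = _linear_problem(30)
        model = bm.fit_boost(X, y, bm.BoostControls(n_iter=5))
        with pytest.raises(ValidationError, match="x"):
            bm.predict_boost(model, pd.DataFrame({"other": [1.0]}))

    def test_json_roundtrip(self):
        X, y = _linear_problem(50)
        model = bm.fit_boost(X, y, bm.BoostControls(n_iter=50))
        again = bm.model_from_json(bm.model_to_json(model))
        np.testing.assert_allclose(
            bm.predict_boost(again, X), bm.predict_boost(model, X)
        )
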