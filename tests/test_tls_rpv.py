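"""Radiomic TLS score: standardization, pre-filter, LASSO, aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tlskit import (
    aggregate_bilateral,
    apply_factors,
    lasso_cv,
    load_published_model,
    prefilter_spearman,
    rpv_score,
    rpv_survival_report,
    standardize,
)
from tlskit.rpv import RpvModel, lambda_max


def feature_frame(rng, n, p, prefix="f"):
    return pd.DataFrame(
        rng.normal(size=(n, p)),
        index=[f"c{i}" for i in range(n)],
        columns=[f"{prefix}{j}" for j in range(p)],
    )


class TestStandardize:
    def test_training_columns_centered_scaled(self, rng):
        X = feature_frame(rng, 30, 4)
        factors, Z = standardize(X)
        assert np.allclose(Z.mean(), 0, atol=1e-12)
        assert np.allclose(Z.std(ddof=1), 1, atol=1e-12)

    def test_reapply_to_training_identical(self, rng):
        X = feature_frame(rng, 20, 3)
        factors, Z = standardize(X)
        Z2 = apply_factors(X, factors)
        assert np.allclose(Z, Z2)

    def test_hand_matrix_exact(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, 10.0, 20.0]})
        factors, Z = standardize(X)
        assert factors.mean["a"] == 2.0 and factors.sd["b"] == 10.0
        assert np.allclose(Z["a"], [-1.0, 0.0, 1.0])

    def test_constant_feature_dropped(self, rng):
        X = feature_frame(rng, 10, 2)
        X["const"] = 5.0
        with pytest.warns(UserWarning, match="const"):
            factors, Z = standardize(X)
        assert "const" not in Z.columns

    def test_missing_test_feature_named(self, rng):
        X = feature_frame(rng, 10, 3)
        factors, _ = standardize(X)
        with pytest.raises(ValueError, match="f2"):
            apply_factors(X.drop(columns="f2"), factors)

    def test_factors_stable_across_applications(self, rng):
        """Training factors are frozen: repeated test transforms reuse them."""
        X = feature_frame(rng, 15, 3)
        factors, _ = standardize(X)
        checksum = factors.checksum()
        for seed in range(3):
            T = feature_frame(np.random.default_rng(seed), 8, 3)
            apply_factors(T, factors)
            assert factors.checksum() == checksum


class TestPrefilter:
    def test_monotone_transform_kept(self, rng):
        y = pd.Series(rng.normal(size=30), index=[f"c{i}" for i in range(30)])
        X = pd.DataFrame({"mono": np.exp(y), "noise": rng.normal(size=30)},
                         index=y.index)
        kept = prefilter_spearman(X, y, threshold=0.99)
        assert kept == ["mono"]

    def test_threshold_one_keeps_nothing_imperfect(self, rng):
        y = pd.Series(rng.normal(size=25), index=[f"c{i}" for i in range(25)])
        X = feature_frame(rng, 25, 5)
        assert prefilter_spearman(X, y, threshold=1.0) == []

    def test_matches_independent_rank_computation(self, rng):
        n = 40
        y = pd.Series(rng.normal(size=n), index=[f"c{i}" for i in range(n)])
        X = feature_frame(rng, n, 50)
        kept = prefilter_spearman(X, y, threshold=0.1)
        ry = y.rank()
        expected = [
            c for c in X.columns
            if abs(np.corrcoef(X[c].rank(), ry)[0, 1]) > 0.1
        ]
        assert kept == expected

    def test_constant_feature_excluded(self, rng):
        y = pd.Series(rng.normal(size=10), index=[f"c{i}" for i in range(10)])
        X = pd.DataFrame({"const": np.ones(10)}, index=y.index)
        assert prefilter_spearman(X, y, threshold=0.0) == []


class TestLassoCv:
    def test_lambda_max_gives_zero_model(self, rng):
        X = feature_frame(rng, 40, 6)
        y = pd.Series(rng.normal(size=40), index=X.index)
        lmax = lambda_max(X.to_numpy(), y.to_numpy())
        model = lasso_cv(X, y, folds=4, lambdas=np.array([lmax * 1.01]))
        assert np.all(model.coefficients == 0)

    def test_orthonormal_soft_threshold(self, rng):
        """On an orthonormal design the LASSO is coordinate-wise soft-thresholding."""
        n, p = 64, 8
        A = rng.normal(size=(n, p))
        A -= A.mean(axis=0)  # columns orthogonal to the intercept
        Q, _ = np.linalg.qr(A)
        X = pd.DataFrame(Q * np.sqrt(n), index=[f"c{i}" for i in range(n)],
                         columns=[f"f{j}" for j in range(p)])  # X'X = n I
        beta = np.array([2.0, -1.5, 0.8, 0.0, 0.0, 0.3, 0.0, -0.1])
        y = pd.Series(X.to_numpy() @ beta + 0.1 * rng.normal(size=n), index=X.index)
        lam = 0.3
        model = lasso_cv(X, y, folds=4, lambdas=np.array([lam]))
        Xa, ya = X.to_numpy(), y.to_numpy() - y.mean()
        w_ols = Xa.T @ ya / n
        expected = np.sign(w_ols) * np.maximum(np.abs(w_ols) - lam, 0.0)
        assert np.max(np.abs(model.coefficients - expected)) < 1e-8

    def test_lambda_zero_matches_least_squares(self, rng):
        n, p = 50, 4
        X = feature_frame(rng, n, p)
        y = pd.Series(rng.normal(size=n), index=X.index)
        model = lasso_cv(X, y, folds=5, lambdas=np.array([0.0]))
        A = np.c_[np.ones(n), X.to_numpy()]
        coef = np.linalg.lstsq(A, y.to_numpy(), rcond=None)[0]
        assert np.max(np.abs(model.coefficients - coef[1:])) < 1e-8

    def test_deterministic_given_seed(self, rng):
        X = feature_frame(rng, 30, 5)
        y = pd.Series(rng.normal(size=30), index=X.index)
        a = lasso_cv(X, y, folds=3, seed=7)
        b = lasso_cv(X, y, folds=3, seed=7)
        assert a.penalty == b.penalty
        assert np.array_equal(a.coefficients, b.coefficients)

    def test_empty_grid_rejected(self, rng):
        X = feature_frame(rng, 10, 2)
        y = pd.Series(rng.normal(size=10), index=X.index)
        with pytest.raises(ValueError, match="grid"):
            lasso_cv(X, y, folds=2, lambdas=np.array([]))

    def test_selects_minimum_cv_error(self, rng):
        X = feature_frame(rng, 60, 5)
        y = pd.Series(X["f0"] * 2 + 0.2 * rng.normal(size=60), index=X.index)
        model = lasso_cv(X, y, folds=5, seed=1)
        curve = model.cv_curve
        assert model.penalty == curve.loc[curve["mean_cv_mse"].idxmin(), "lambda"]


class TestRpvScore:
    def test_origin_maps_to_zero(self):
        model = load_published_model()
        feats = pd.Series(0.0, index=model.features)
        assert rpv_score(feats, model) == 0.0

    def test_published_unit_entropy(self):
        model = load_published_model()
        feats = pd.Series([1.0, 0.0, 0.0], index=model.features)
        assert rpv_score(feats, model) == pytest.approx(0.109)

    def test_published_sum_of_coefficients(self):
        model = load_published_model()
        feats = pd.Series([1.0, 1.0, 1.0], index=model.features)
        assert rpv_score(feats, model) == pytest.approx(0.0557)

    def test_missing_feature_error(self):
        model = load_published_model()
        with pytest.raises(ValueError, match="GLCM"):
            rpv_score(pd.Series({"other": 1.0}), model)

    def test_json_round_trip(self, tmp_path):
        model = load_published_model()
        model.to_json(tmp_path / "m.json")
        back = RpvModel.from_json(tmp_path / "m.json")
        assert back.features == model.features
        assert np.array_equal(back.coefficients, model.coefficients)


class TestAggregateBilateral:
    def test_single_mass_identity(self):
        df = pd.DataFrame({"case_id": ["a"], "rpv_score": [0.3]})
        assert aggregate_bilateral(df)["a"] == 0.3

    def test_bilateral_takes_max(self):
        df = pd.DataFrame({"case_id": ["a", "a"], "rpv_score": [0.2, 0.5]})
        assert aggregate_bilateral(df)["a"] == 0.5

    def test_permutation_invariant(self, rng):
        df = pd.DataFrame({"case_id": ["a", "a", "b", "b", "b"],
                           "rpv_score": [0.1, 0.4, -0.2, 0.9, 0.3]})
        a = aggregate_bilateral(df)
        b = aggregate_bilateral(df.sample(frac=1, random_state=2))
        assert a.equals(b.sort_index())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_bilateral(pd.DataFrame(columns=["case_id", "rpv_score"]))


class TestSurvivalReport:
    def _clinical(self, rng, n, scores=None, protective=False):
        if protective:
            lp = -1.5 * (scores - scores.mean()) / scores.std()
            t = rng.exponential(1.0, n) / (0.05 * np.exp(lp))
        else:
            t = rng.exponential(20.0, n)
        return pd.DataFrame({
            "time_months": t + 0.01,
            "event": rng.random(n) < 0.8,
        }, index=scores.index).astype({"event": int})

    def test_median_cut_group_sizes(self, rng):
        n = 21
        scores = pd.Series(rng.permutation(n).astype(float),
                           index=[f"c{i}" for i in range(n)])
        clin = self._clinical(rng, n, scores)
        rep = rpv_survival_report(scores, clin, cut_quantile=0.5)
        sizes = rep["labels"].value_counts()
        assert set(sizes) == {10, 11}

    def test_protective_score_detected(self, rng):
        n = 200
        scores = pd.Series(rng.normal(size=n), index=[f"c{i}" for i in range(n)])
        clin = self._clinical(rng, n, scores, protective=True)
        rep = rpv_survival_report(scores, clin)
        assert rep["logrank_p"] < 0.05
        assert rep["cox"].hr[0] < 1.0

    def test_null_score_ci_covers_one(self):
        covered = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 120
            scores = pd.Series(r.normal(size=n), index=[f"c{i}" for i in range(n)])
            clin = self._clinical(r, n, scores)
            rep = rpv_survival_report(scores, clin)
            lo, hi = rep["cox"].ci_low[0], rep["cox"].ci_high[0]
            covered += lo <= 1.0 <= hi
        assert covered >= 8
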