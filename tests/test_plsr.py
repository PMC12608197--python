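"""SIMPLS fits, cross-validation, and metrics against independent oracles."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

import leafspec as ls
from leafspec.plsr import subset_rmsecv


@pytest.fixture()
def random_xy():
    rng = np.random.default_rng(0)
    X = rng.random((40, 12))
    beta = rng.normal(size=12)
    y = X @ beta + 0.01 * rng.normal(size=40)
    return X, y


class TestFit:
    def test_exact_linear_fit_limit(self):
        rng = np.random.default_rng(1)
        X = rng.random((30, 5))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0, -1.0]) + 0.7
        model = ls.fit_plsr(X, y, n_components=5)
        np.testing.assert_allclose(ls.predict(model, X), y, atol=1e-8)

    def test_full_rank_equals_ols(self, random_xy):
        X, y = random_xy
        model = ls.fit_plsr(X, y, n_components=12)
        # normal-equations oracle on centered data
        Xc = X - X.mean(axis=0)
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ (y - y.mean()))
        ols_pred = Xc @ beta + y.mean()
        np.testing.assert_allclose(ls.predict(model, X), ols_pred, atol=1e-8)

    def test_single_column_equals_univariate_slope(self):
        rng = np.random.default_rng(2)
        x = rng.random(25)
        y = 3.0 * x + rng.normal(0, 0.1, 25)
        model = ls.fit_plsr(x[:, None], y, n_components=1)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert model.coef[0] == pytest.approx(slope, rel=1e-10)

    def test_matches_sklearn_nipals(self, random_xy):
        X, y = random_xy
        for k in (1, 3, 6):
            model = ls.fit_plsr(X, y, n_components=k)
            sk = PLSRegression(n_components=k, scale=False).fit(X, y)
            np.testing.assert_allclose(model.coef, sk.coef_.ravel(), atol=1e-9)

    def test_deterministic_bit_identical(self, random_xy):
        X, y = random_xy
        a = ls.fit_plsr(X, y, 4)
        b = ls.fit_plsr(X, y, 4)
        assert np.array_equal(a.coef, b.coef) and a.intercept == b.intercept

    def test_constant_response_rejected(self):
        X = np.random.default_rng(3).random((10, 4))
        with pytest.raises(ValueError, match="constant"):
            ls.fit_plsr(X, np.full(10, 1.5), 2)

    def test_json_roundtrip(self, random_xy, tmp_path):
        X, y = random_xy
        model = ls.fit_plsr(X, y, 3, wavelengths_nm=500.0 + np.arange(12))
        model.to_json(tmp_path / "m.json")
        back = ls.PLSRModel.from_json(tmp_path / "m.json")
        np.testing.assert_array_equal(back.coef, model.coef)
        np.testing.assert_allclose(ls.predict(back, X), ls.predict(model, X))


class TestCrossValidation:
    def test_recovers_planted_latent_dimension(self):
        rng = np.random.default_rng(4)
        n, p, true_k = 120, 30, 3
        scores = rng.normal(size=(n, true_k))
        loadings = rng.normal(size=(true_k, p))
        X = scores @ loadings + 0.001 * rng.normal(size=(n, p))
        y = scores @ np.array([2.0, -1.0, 0.5]) + 0.001 * rng.normal(size=n)
        k, _ = ls.cv_select_components(X, y, max_components=8, seed=0)
        assert k == true_k

    def test_max_one_component(self, random_xy):
        X, y = random_xy
        k, curve = ls.cv_select_components(X, y, max_components=1)
        assert k == 1 and curve.size == 1

    def test_matches_manual_fold_loop(self, random_xy):
        X, y = random_xy
        seed, folds, kmax = 7, 5, 4
        curve = ls.rmsecv(X, y, max_components=kmax, folds=folds, seed=seed)
        # independent oracle: explicit fold loop with sklearn PLS per fold
        perm = np.random.default_rng(seed).permutation(len(y))
        blocks = np.array_split(perm, folds)
        for k in range(1, kmax + 1):
            sq = 0.0
            for val in blocks:
                train = np.setdiff1d(np.arange(len(y)), val)
                sk = PLSRegression(n_components=k, scale=False).fit(X[train], y[train])
                sq += ((sk.predict(X[val]).ravel() - y[val]) ** 2).sum()
            assert curve[k - 1] == pytest.approx(np.sqrt(sq / len(y)), abs=1e-10)

    def test_more_folds_than_samples_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="folds"):
            ls.rmsecv(rng.random((5, 3)), rng.random(5), folds=10)

    def test_subset_rmsecv_first_minimum_on_ties(self, random_xy):
        X, y = random_xy
        rmse, k = subset_rmsecv(X, y, np.arange(12), max_components=6, folds=5, seed=1)
        curve = ls.rmsecv(X, y, max_components=6, folds=5, seed=1)
        assert rmse == curve.min() and k == int(np.argmin(curve)) + 1


class TestEvaluate:
    def test_perfect_prediction(self):
        rng = np.random.default_rng(6)
        X = rng.random((20, 3))
        y = X @ np.ones(3)
        model = ls.fit_plsr(X, y, 3)
        rep = ls.evaluate(model, X, y, "calibration")
        assert rep.r == pytest.approx(1.0)
        assert rep.rmse == pytest.approx(0.0, abs=1e-9)

    def test_hand_formula_oracle(self):
        y = np.array([1.0, 2.0, 3.0])
        yhat = np.array([1.1, 1.9, 3.2])
        model = ls.PLSRModel(
            coef=np.array([1.0]), intercept=0.0, n_components=1,
            x_mean=np.zeros(1), y_mean=0.0, channels=np.array([0]),
        )
        rep = ls.evaluate(model, yhat[:, None], y, "prediction")
        assert rep.rmse == pytest.approx(np.sqrt(0.06 / 3))
        assert rep.r == pytest.approx(np.corrcoef(yhat, y)[0, 1])
        assert rep.rpd == pytest.approx(np.std(y, ddof=1) / np.sqrt(0.02))

    def test_constant_prediction_flags_r(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        model = ls.PLSRModel(
            coef=np.array([0.0]), intercept=float(y.mean()), n_components=1,
            x_mean=np.zeros(1), y_mean=float(y.mean()), channels=np.array([0]),
        )
        rep = ls.evaluate(model, y[:, None], y, "prediction")
        assert np.isnan(rep.r)
        assert rep.rmse == pytest.approx(np.std(y))  # population SD of y

    def test_channel_permutation_invariance(self, random_xy):
        X, y = random_xy
        model = ls.fit_plsr(X, y, 4)
        perm = np.random.default_rng(8).permutation(12)
        permuted = ls.PLSRModel(
            coef=model.coef[perm], intercept=model.intercept,
            n_components=model.n_components, x_mean=model.x_mean[perm],
            y_mean=model.y_mean, channels=np.arange(12),
        )
        a = ls.evaluate(model, X, y, "calibration")
        b = ls.evaluate(permuted, X[:, perm], y, "calibration")
        assert a.rmse == pytest.approx(b.rmse) and a.r == pytest.approx(b.r)

    def test_too_few_samples_rejected(self):
        model = ls.PLSRModel(
            coef=np.array([1.0]), intercept=0.0, n_components=1,
            x_mean=np.zeros(1), y_mean=0.0, channels=np.array([0]),
        )
        with pytest.raises(ValueError, match="at least 2"):
            ls.evaluate(model, np.array([[1.0]]), np.array([1.0]), "prediction")
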