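"""PLS1 core: NIPALS correctness, PRESS leave-one-out, component selection, VIP."""

import numpy as np
import pytest

from wheatgpc import (
    PLSModel,
    fit_pls,
    fit_ols,
    predict,
    press_curve,
    select_components,
    vip_scores,
)
from wheatgpc.errors import ModelFitError
from wheatgpc.pls import PRESSCurve, predict_via_latent

from conftest import PAPER_COEFFICIENTS, PAPER_INTERCEPT, PAPER_PREDICTORS


def random_instance(rng, n=40, p=5, noise=0.3):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + rng.normal(0, noise, n)
    return X, y


def brute_force_press(X, y, a_max):
    """Independent LOO oracle: refit every fold at every component count."""
    n = X.shape[0]
    press = np.zeros(a_max)
    for a in range(1, a_max + 1):
        for i in range(n):
            keep = np.arange(n) != i
            model = fit_pls(X[keep], y[keep], a)
            yhat = predict(model, X[i : i + 1])[0]
            press[a - 1] += (y[i] - yhat) ** 2
    return press


class TestFit:
    def test_noiseless_univariate(self):
        x = np.linspace(0, 1, 10)[:, None]
        y = 2.0 * x.ravel()
        m = fit_pls(x, y, 1)
        assert m.coefficients[0] == pytest.approx(2.0, abs=1e-10)
        assert m.intercept == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(predict(m, x), y, atol=1e-10)

    def test_full_components_equal_ols(self, rng):
        X, y = random_instance(rng, n=50, p=6)
        m = fit_pls(X, y, 6)
        ols = fit_ols(X, y)
        np.testing.assert_allclose(predict(m, X), ols.predict(X), atol=1e-8)

    def test_agrees_with_sklearn_nipals(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = random_instance(rng, n=60, p=5)
        for a in (1, 3, 5):
            m = fit_pls(X, y, a)
            sk = sklearn.PLSRegression(n_components=a, scale=True).fit(X, y)
            np.testing.assert_allclose(m.coefficients, sk.coef_.ravel(), atol=1e-9)

    def test_score_orthogonality(self, rng):
        X, y = random_instance(rng, n=80, p=8)
        m = fit_pls(X, y, 6)
        Xs = (X - m.x_means) / m.x_scales
        # rebuild scores by deflation
        T = np.zeros((80, 6))
        Xd = Xs.copy()
        for k in range(6):
            T[:, k] = Xd @ m.weights[:, k]
            Xd = Xd - np.outer(T[:, k], m.x_loadings[:, k])
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_latent_and_coefficient_paths_agree(self, rng):
        X, y = random_instance(rng, n=40, p=5)
        m = fit_pls(X, y, 3)
        Xnew = rng.normal(size=(15, 5))
        np.testing.assert_allclose(
            predict_via_latent(m, Xnew), predict(m, Xnew), atol=1e-10
        )

    def test_excess_components_refused(self, rng):
        X = rng.normal(size=(20, 3))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])  # rank 3, p=4
        y = rng.normal(size=20)
        with pytest.raises(ModelFitError, match="rank"):
            fit_pls(X, y, 4)

    def test_zero_variance_column_named(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 7.0
        with pytest.raises(ModelFitError, match="x2"):
            fit_pls(X, rng.normal(size=20), 1)

    def test_too_few_samples_refused(self, rng):
        X = rng.normal(size=(3, 4))
        with pytest.raises(ModelFitError, match="n >="):
            fit_pls(X, rng.normal(size=3), 3)

    def test_parameter_recovery_on_collinear_synthetic(self, rng):
        """Coefficients recovered within 3 OLS standard errors of truth."""
        n, p = 200, 4
        latent = rng.normal(size=(n, 2))
        X = latent @ rng.normal(size=(2, p)) + rng.normal(0, 0.2, (n, p))
        beta = np.array([3.9, 1.7, 2.9, -1.3])
        y = X @ beta + rng.normal(0, 0.3, n)
        m = fit_pls(X, y, p)
        Xd = np.column_stack([np.ones(n), X])
        resid = y - predict(m, X)
        sigma2 = resid @ resid / (n - p - 1)
        cov = sigma2 * np.linalg.inv(Xd.T @ Xd)
        se = np.sqrt(np.diag(cov))[1:]
        assert np.all(np.abs(m.coefficients - beta) < 3 * se)


class TestPredict:
    def paper_model(self):
        return PLSModel.from_coefficients(PAPER_PREDICTORS, PAPER_COEFFICIENTS, PAPER_INTERCEPT)

    def test_published_intercept_at_zero_input(self):
        m = self.paper_model()
        assert predict(m, np.zeros((1, 4)))[0] == pytest.approx(5.821, abs=1e-12)

    def test_published_unit_ndvi(self):
        m = self.paper_model()
        x = np.array([[1.0, 0.0, 0.0, 0.0]])
        assert predict(m, x)[0] == pytest.approx(9.694, abs=1e-12)

    def test_published_worked_point(self):
        m = self.paper_model()
        x = np.array([[0.8, 0.9, 0.1, 0.6]])
        assert predict(m, x)[0] == pytest.approx(9.9664, abs=1e-10)

    def test_name_mismatch_rejected(self, table_255):
        m = self.paper_model()
        wrong = table_255.data[["NDVI", "SIPI", "EVI", "PSRI"]]  # swapped order
        with pytest.raises(ModelFitError, match="match"):
            predict(m, wrong)

    def test_serialization_round_trip(self, rng, tmp_path):
        X, y = random_instance(rng, n=40, p=5)
        m = fit_pls(X, y, 3)
        path = tmp_path / "model.json"
        m.save(path)
        back = PLSModel.load(path)
        Xnew = rng.normal(size=(10, 5))
        np.testing.assert_allclose(predict(back, Xnew), predict(m, Xnew), atol=1e-12)


class TestPress:
    def test_perfect_linear_data_zero_press(self):
        x = np.linspace(0, 1, 12)[:, None]
        y = 2.0 * x.ravel() + 1.0
        curve = press_curve(x, y, 1)
        assert curve.press[0] < 1e-16
        assert curve.k == 12

    @pytest.mark.parametrize("n,p,a_max", [(6, 2, 2), (8, 3, 3), (12, 4, 4), (10, 5, 3)])
    def test_matches_brute_force_oracle(self, n, p, a_max):
        rng = np.random.default_rng(n * 100 + p)
        X, y = random_instance(rng, n=n, p=p)
        curve = press_curve(X, y, a_max)
        oracle = brute_force_press(X, y, a_max)
        np.testing.assert_allclose(curve.press, oracle, atol=1e-10)

    def test_overfitting_rise_after_minimum(self):
        """Pure-noise responses: the PRESS curve rises past its minimum in
        most replicates (chasing noise with extra components hurts LOO skill)."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 6))
            y = rng.normal(size=40)
            curve = press_curve(X, y, 6)
            i = int(np.argmin(curve.press))
            if i == len(curve.press) - 1 or curve.press[-1] >= curve.press[i]:
                hits += 1
        assert hits >= 40

    def test_too_small_n_rejected(self, rng):
        X, y = random_instance(rng, n=5, p=4)
        with pytest.raises(ModelFitError):
            press_curve(X, y, 4)


class TestSelect:
    def test_argmin(self):
        curve = PRESSCurve(a_values=np.arange(1, 6), press=np.array([30, 25, 21.39, 22, 28]), k=10)
        assert select_components(curve) == 3

    def test_strictly_decreasing_selects_amax(self):
        curve = PRESSCurve(a_values=np.arange(1, 5), press=np.array([4.0, 3.0, 2.0, 1.0]), k=10)
        assert select_components(curve) == 4

    def test_tie_breaks_to_smallest(self):
        curve = PRESSCurve(a_values=np.arange(1, 4), press=np.array([10.0, 10.0, 12.0]), k=10)
        assert select_components(curve) == 1


class TestVIP:
    def test_single_predictor_vip_is_one(self):
        x = np.linspace(0, 1, 20)[:, None]
        y = 3 * x.ravel() + np.sin(np.arange(20))
        m = fit_pls(x, y, 1)
        assert vip_scores(m).iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_informative_predictor_ranks_above_noise(self):
        rng = np.random.default_rng(8)
        x1 = rng.normal(size=100)
        x2 = rng.normal(size=100)
        y = 2 * x1 + rng.normal(0, 0.1, 100)
        m = fit_pls(np.column_stack([x1, x2]), y, 2)
        vip = vip_scores(m)
        assert vip.iloc[0] > 1 > vip.iloc[1]

    def test_squared_vips_average_to_one(self, rng):
        for _ in range(5):
            X, y = random_instance(rng, n=30, p=6)
            m = fit_pls(X, y, 3)
            assert np.mean(vip_scores(m) ** 2) == pytest.approx(1.0, abs=1e-10)
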