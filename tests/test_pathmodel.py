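"""The ML covariance-structure estimator and its fit statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from movecoda.pathmodel import (
    FitIndices,
    ModelSpec,
    fit_indices,
    fit_ml,
    implied_covariance,
    model_df,
    satorra_bentler_scale,
)


def _saturated3():
    spec = ModelSpec(["a", "b", "c"])
    spec.add_cov("a", "b")
    spec.add_cov("a", "c")
    spec.add_cov("b", "c")
    return spec


def _chain_spec():
    spec = ModelSpec(["x", "m", "y"])
    spec.add_path("m", "x")
    spec.add_path("y", "m")
    return spec


class TestModelSpec:
    def test_df_arithmetic(self):
        # 3 variables: 6 moments; chain has 2 paths + 3 variances -> df 1
        assert model_df(_chain_spec()) == 1
        assert model_df(_saturated3()) == 0

    def test_cycle_detection(self):
        spec = ModelSpec(["a", "b"])
        spec.add_path("a", "b")
        spec.add_path("b", "a")
        with pytest.raises(ValueError, match="cycle"):
            spec.check_acyclic()

    def test_serialisation_round_trip(self):
        spec = _chain_spec()
        spec.add_path("y", "x", free=False, value=0.5)
        d = spec.to_dict()
        spec2 = ModelSpec.from_dict(d)
        assert spec2.to_dict() == d
        assert spec2.n_free == spec.n_free

    def test_unknown_variable_rejected(self):
        spec = ModelSpec(["a"])
        with pytest.raises(ValueError):
            spec.add_path("a", "zz")


class TestImpliedCovariance:
    def test_no_paths_gives_diagonal(self):
        spec = ModelSpec(["a", "b"])
        spec.add_cov("a", "a", free=False, value=2.0)
        spec.add_cov("b", "b", free=False, value=3.0)
        assert np.allclose(implied_covariance(spec), np.diag([2.0, 3.0]))

    def test_single_regression_closed_form(self):
        spec = ModelSpec(["x", "y"])
        spec.add_path("y", "x", free=False, value=0.7)
        spec.add_cov("x", "x", free=False, value=2.0)
        spec.add_cov("y", "y", free=False, value=1.0)
        sigma = implied_covariance(spec)
        assert sigma[0, 1] == pytest.approx(0.7 * 2.0)
        assert sigma[1, 1] == pytest.approx(0.7**2 * 2.0 + 1.0)

    def test_recursive_toy_against_monte_carlo(self, rng):
        """Implied covariance of a 4-variable recursive system vs the
        empirical covariance of data simulated from the same equations."""
        spec = ModelSpec(["a", "b", "c", "d"])
        for y, x, v in [("b", "a", 0.5), ("c", "b", -0.8), ("d", "a", 0.3), ("d", "c", 0.6)]:
            spec.add_path(y, x, free=False, value=v)
        for v, s in zip("abcd", [1.0, 0.8, 1.2, 0.5]):
            spec.add_cov(v, v, free=False, value=s)
        sigma = implied_covariance(spec)
        n = 10**6
        a = rng.normal(0, 1.0, n)
        b = 0.5 * a + rng.normal(0, np.sqrt(0.8), n)
        c = -0.8 * b + rng.normal(0, np.sqrt(1.2), n)
        d = 0.3 * a + 0.6 * c + rng.normal(0, np.sqrt(0.5), n)
        emp = np.cov(np.stack([a, b, c, d]))
        assert np.max(np.abs(sigma - emp)) < 0.01


class TestFitMl:
    def test_saturated_model_has_zero_statistic(self, rng):
        X = rng.multivariate_normal([0, 0, 0], [[1, 0.5, 0.3], [0.5, 1, 0.2], [0.3, 0.2, 1]], 400)
        f = fit_ml(np.cov(X, rowvar=False), 400, _saturated3())
        assert f.df == 0
        assert f.chi2 < 1e-6
        assert f.converged

    def test_single_path_equals_ols(self, rng):
        X = rng.multivariate_normal([0, 0], [[2.0, 0.8], [0.8, 1.5]], 300)
        S = np.cov(X, rowvar=False)
        spec = ModelSpec(["x", "y"])
        spec.add_path("y", "x")
        f = fit_ml(S, 300, spec)
        assert f.estimates["y ~ x"] == pytest.approx(S[0, 1] / S[0, 0], abs=1e-6)

    def test_recursive_saturated_paths_equal_least_squares(self, rng):
        """Fully recursive model with free residual covariances: every
        path estimate must match the equation-wise OLS solution."""
        n = 500
        R = np.array(
            [[1, 0.3, 0.2, 0.1], [0.3, 1, 0.4, 0.2], [0.2, 0.4, 1, 0.3], [0.1, 0.2, 0.3, 1]]
        )
        X = rng.multivariate_normal(np.zeros(4), R, n)
        S = np.cov(X, rowvar=False)
        spec = ModelSpec(["x1", "x2", "m", "y"])
        spec.add_cov("x1", "x2")
        for pred in ("x1", "x2"):
            spec.add_path("m", pred)
            spec.add_path("y", pred)
        spec.add_path("y", "m")
        f = fit_ml(S, n, spec)
        assert f.df == 0 and f.chi2 < 1e-6
        # OLS oracle for each equation
        bm = np.linalg.solve(S[:2, :2], S[:2, 2])
        by = np.linalg.solve(S[:3, :3], S[:3, 3])
        assert f.estimates["m ~ x1"] == pytest.approx(bm[0], abs=1e-6)
        assert f.estimates["m ~ x2"] == pytest.approx(bm[1], abs=1e-6)
        assert f.estimates["y ~ x1"] == pytest.approx(by[0], abs=1e-6)
        assert f.estimates["y ~ m"] == pytest.approx(by[2], abs=1e-6)

    def test_recovers_generating_parameters_from_implied_sigma(self):
        """Self-consistency: fitting the model to its own implied
        covariance returns the generating parameter values."""
        gen = ModelSpec(["x", "m", "y"])
        gen.add_path("m", "x", free=False, value=0.4)
        gen.add_path("y", "m", free=False, value=-0.6)
        gen.add_path("y", "x", free=False, value=0.2)
        for v, s in zip("xmy", [1.5, 0.9, 1.1]):
            gen.add_cov(v, v, free=False, value=s)
        sigma = implied_covariance(gen)
        spec = ModelSpec(["x", "m", "y"])
        spec.add_path("m", "x")
        spec.add_path("y", "m")
        spec.add_path("y", "x")
        f = fit_ml(sigma, 1000, spec)
        assert f.estimates["m ~ x"] == pytest.approx(0.4, abs=1e-6)
        assert f.estimates["y ~ m"] == pytest.approx(-0.6, abs=1e-6)
        assert f.estimates["y ~ x"] == pytest.approx(0.2, abs=1e-6)
        assert f.estimates["x ~~ x"] == pytest.approx(1.5, abs=1e-6)
        assert f.chi2 < 1e-8

    def test_fixed_parameters_are_respected(self, rng):
        X = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], 200)
        spec = ModelSpec(["x", "y"])
        spec.add_path("y", "x", free=False, value=0.0)
        f = fit_ml(np.cov(X, rowvar=False), 200, spec)
        assert f.estimates["y ~ x"] == 0.0
        assert f.df == 1

    def test_not_identified_raises(self):
        spec = _saturated3()
        spec.add_path("a", "b")  # one parameter too many
        with pytest.raises(ValueError, match="identified"):
            fit_ml(np.eye(3), 100, spec)

    def test_non_pd_sample_covariance_raises(self):
        S = np.ones((3, 3))
        with pytest.raises(ValueError, match="positive definite"):
            fit_ml(S, 100, _saturated3())

    def test_labelled_dataframe_input_is_reordered(self, rng):
        X = rng.multivariate_normal([0, 0], [[2.0, 0.8], [0.8, 1.5]], 300)
        S = pd.DataFrame(np.cov(X, rowvar=False), index=["x", "y"], columns=["x", "y"])
        spec = ModelSpec(["y", "x"])  # reversed order
        spec.add_path("y", "x")
        f = fit_ml(S.loc[["y", "x"], ["y", "x"]], 300, spec)
        assert f.estimates["y ~ x"] == pytest.approx(S.loc["x", "y"] / S.loc["x", "x"], abs=1e-6)


class TestStandardErrors:
    def test_ols_slope_se_closed_form(self, rng):
        n = 200
        x = rng.normal(0, 1.3, n)
        y = 0.5 * x + rng.normal(0, 0.9, n)
        S = np.cov(np.stack([x, y]))
        spec = ModelSpec(["x", "y"])
        spec.add_path("y", "x")
        f = fit_ml(S, n, spec)
        resid_var = S[1, 1] - S[0, 1] ** 2 / S[0, 0]
        se_ols = np.sqrt(resid_var / ((n - 1) * S[0, 0]))
        assert f.se["y ~ x"] == pytest.approx(se_ols, rel=0.02)

    def test_saturated_variance_se_wishart_closed_form(self, rng):
        n = 500
        x = rng.normal(0, 2.0, n)
        S = np.atleast_2d(np.var(x, ddof=1))
        spec = ModelSpec(["x"])
        f = fit_ml(S, n, spec)
        assert f.se["x ~~ x"] == pytest.approx(np.sqrt(2.0 / (n - 1)) * S[0, 0], rel=1e-6)


class TestStandardizedSolution:
    def test_equals_raw_on_standardized_data(self, rng):
        X = rng.multivariate_normal([0, 0, 0], [[1, 0.5, 0.3], [0.5, 1, 0.2], [0.3, 0.2, 1]], 500)
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        S = np.cov(X, rowvar=False)
        f = fit_ml(S, 500, _chain_spec())
        std = f.standardized()
        assert std["m ~ x"] == pytest.approx(f.estimates["m ~ x"], abs=1e-9)

    def test_invariant_to_predictor_rescaling(self, rng):
        X = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], 400)
        S1 = np.cov(X, rowvar=False)
        X2 = X.copy()
        X2[:, 0] *= 10.0
        S2 = np.cov(X2, rowvar=False)
        spec1 = ModelSpec(["x", "y"]); spec1.add_path("y", "x")
        spec2 = ModelSpec(["x", "y"]); spec2.add_path("y", "x")
        b1 = fit_ml(S1, 400, spec1).standardized()["y ~ x"]
        b2 = fit_ml(S2, 400, spec2).standardized()["y ~ x"]
        assert b1 == pytest.approx(b2, abs=1e-9)


class TestFitIndices:
    def test_boundary_values(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        fi = fit_indices(T=5.0, df=5, n=100, S=S, sigma=S)
        assert fi.rmsea == 0.0
        assert fi.srmr == 0.0
        assert fi.cfi == 1.0

    def test_rmsea_closed_form_arithmetic(self):
        S = np.eye(3)
        fi = fit_indices(T=20.19, df=12, n=201, S=S, sigma=S)
        assert fi.rmsea == pytest.approx(np.sqrt(8.19 / (12 * 200)), abs=1e-12)
        assert round(fi.rmsea, 3) == 0.058

    def test_rmsea_ci_brackets_point_estimate(self):
        S = np.eye(3)
        fi = fit_indices(T=20.19, df=12, n=201, S=S, sigma=S)
        lo, hi = fi.rmsea_ci
        assert 0.0 <= lo <= fi.rmsea <= hi
        # upper bound solves the noncentral-chi2 equation
        lam_hi = hi**2 * 12 * 200
        assert stats.ncx2.cdf(20.19, 12, lam_hi) == pytest.approx(0.05, abs=1e-6)

    def test_independence_data_give_cfi_zero_baseline(self, rng):
        # fitting the independence structure to correlated data: CFI -> 0
        X = rng.multivariate_normal([0, 0], [[1, 0.9], [0.9, 1]], 500)
        S = np.cov(X, rowvar=False)
        spec = ModelSpec(["x", "y"])
        spec.add_cov("x", "y", free=False, value=0.0)
        f = fit_ml(S, 500, spec)
        assert f.indices.cfi == pytest.approx(0.0, abs=1e-9)
        assert f.indices.srmr > 0.5


class TestSatorraBentler:
    def test_scaling_factor_near_one_under_normality(self, rng):
        R = np.array([[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1]])
        X = rng.multivariate_normal(np.zeros(3), R, 5000)
        f = fit_ml(np.cov(X, rowvar=False), 5000, _chain_spec())
        scaled, c = satorra_bentler_scale(X, f)
        assert c == pytest.approx(1.0, abs=0.1)
        assert scaled == pytest.approx(f.chi2 / c)

    def test_scaling_factor_exceeds_one_for_heavy_tails(self, rng):
        """Elliptical multivariate-t data: the common-kurtosis theory value
        is (nu-2)/(nu-4) > 1."""
        R = np.array([[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1]])
        Z = rng.multivariate_normal(np.zeros(3), R, 8000)
        W = rng.chisquare(10, 8000) / 10.0
        X = Z / np.sqrt(W)[:, None]
        f = fit_ml(np.cov(X, rowvar=False), 8000, _chain_spec())
        _, c = satorra_bentler_scale(X, f)
        assert c > 1.1

    def test_undefined_for_saturated_model(self, rng):
        X = rng.multivariate_normal(np.zeros(3), np.eye(3), 500)
        f = fit_ml(np.cov(X, rowvar=False), 500, _saturated3())
        with pytest.raises(ValueError, match="df = 0"):
            satorra_bentler_scale(X, f)
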