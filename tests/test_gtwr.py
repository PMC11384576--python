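"""GTWR engine: kernels, local WLS, hat diagnostics, CV, bandwidth search."""

import math

import numpy as np
import pytest

import hpagtwr as h
from hpagtwr.errors import (BandwidthError, InvalidArgumentError,
                            SingularityError)
from hpagtwr.gtwr import ObservationPoint, _st_distance_matrix


def obs(u, v, t):
    return ObservationPoint(city_id=0, u=u, v=v, t=t)


class TestDistance:
    def test_identical_point(self):
        assert h.st_distance_sq(obs(1, 2, 2020), obs(1, 2, 2020), 1, 1) == 0.0

    def test_spatial_345(self):
        assert h.st_distance_sq(obs(0, 0, 2020), obs(3, 4, 2020), 1, 0) == 25.0

    def test_combined(self):
        assert h.st_distance_sq(obs(0, 0, 2018), obs(3, 4, 2020), 2, 1) == 54.0

    def test_invalid_scales(self):
        with pytest.raises(InvalidArgumentError):
            h.st_distance_sq(obs(0, 0, 0), obs(1, 1, 1), 0, 0)


class TestKernel:
    def test_zero_distance(self):
        assert h.kernel_weight(0.0, 5.0) == 1.0

    def test_gaussian_at_h(self):
        assert h.kernel_weight(4.0, 2.0) == pytest.approx(math.exp(-1))

    def test_large_bandwidth_limit(self):
        assert h.kernel_weight(100.0, 1e9) == pytest.approx(1.0)

    def test_bisquare(self):
        assert h.kernel_weight(1.0, 2.0, "bisquare") == pytest.approx(0.5625)
        assert h.kernel_weight(5.0, 2.0, "bisquare") == 0.0

    def test_invalid_bandwidth(self):
        with pytest.raises(InvalidArgumentError):
            h.kernel_weight(1.0, 0.0)


class TestFitLocal:
    def test_unit_weights_equal_ols(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
        y = rng.normal(size=30)
        beta = h.fit_local(X, y, np.ones(30))
        expected, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(beta, expected, atol=1e-12)

    def test_exact_linear_any_weights(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = X @ np.array([1.0, -3.0])
        w = rng.uniform(0.1, 1.0, size=20)
        beta = h.fit_local(X, y, w)
        np.testing.assert_allclose(beta, [1.0, -3.0], atol=1e-10)

    def test_three_point_normal_equations_oracle(self):
        # independent explicit (X'WX)^{-1} X'Wy computation
        X = np.array([[1.0, 1.0], [1.0, 2.0], [1.0, 4.0]])
        y = np.array([2.0, 3.0, 7.0])
        w = np.array([1.0, 0.5, 0.25])
        W = np.diag(w)
        expected = np.linalg.inv(X.T @ W @ X) @ X.T @ W @ y
        np.testing.assert_allclose(h.fit_local(X, y, w), expected, atol=1e-12)

    def test_random_instances_match_normal_equations(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n, k = rng.integers(5, 50), rng.integers(1, 4)
            X = np.column_stack([np.ones(n), rng.normal(size=(n, k))])
            y = rng.normal(size=n)
            w = rng.uniform(0.01, 2.0, size=n)
            expected = np.linalg.solve(X.T @ np.diag(w) @ X,
                                       X.T @ np.diag(w) @ y)
            np.testing.assert_allclose(h.fit_local(X, y, w), expected,
                                       atol=1e-10)

    def test_singular_design_raises(self):
        X = np.ones((10, 2))  # duplicate columns
        with pytest.raises(SingularityError):
            h.fit_local(X, np.ones(10), np.ones(10))

    def test_too_few_positive_weights(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        w = np.array([1.0, 0, 0, 0, 0])
        with pytest.raises(SingularityError):
            h.fit_local(X, np.ones(5), w)


class TestFitGtwr:
    def test_flat_kernel_limit_matches_ols(self, noisy_panel):
        fit = h.fit_gtwr(noisy_panel, h.STKernelParams(h=1e9, mu_t=1.0))
        ols = h.fit_ols(noisy_panel)
        assert np.abs(fit.coefficients - ols.coefficients).max() < 1e-6
        assert fit.aicc == pytest.approx(ols.aicc, abs=1e-3)

    def test_zero_noise_constant_surfaces_fit_exactly(self, constant_panel):
        panel, _ = constant_panel
        for bw in (5.0, 50.0, 1e6):
            fit = h.fit_gtwr(panel, h.STKernelParams(h=bw, mu_t=1.0))
            assert np.abs(fit.residuals).max() < 1e-8

    def test_hat_diag_and_trace_bounds(self, noisy_panel):
        fit = h.fit_gtwr(noisy_panel, h.STKernelParams(h=30.0, mu_t=10.0))
        p = len(noisy_panel.var_names)
        assert np.all(fit.hat_diag >= -1e-10)
        assert np.all(fit.hat_diag <= 1.0 + 1e-10)
        assert p - 1e-8 <= fit.trace_s <= fit.n
        assert fit.adj_r2 <= 1.0

    def test_tiny_bandwidth_rejected(self, noisy_panel):
        with pytest.raises((BandwidthError, SingularityError)):
            h.fit_gtwr(noisy_panel, h.STKernelParams(h=1e-3, mu_t=1.0))

    def test_parameter_recovery_on_gradient_panel(self, gradient_panel):
        from conftest import fit_cv
        panel, truth = gradient_panel
        fit = fit_cv(panel)
        for j in range(truth.shape[1]):
            r = np.corrcoef(fit.coefficients[:, j], truth.iloc[:, j])[0, 1]
            assert r >= 0.8, f"poor recovery for {truth.columns[j]}: r={r:.3f}"

    def test_model_selection_direction_on_gradient_panel(self, gradient_panel):
        from conftest import fit_cv
        panel, _ = gradient_panel
        fit = fit_cv(panel)
        ols = h.fit_ols(panel)
        assert fit.aicc < ols.aicc
        assert fit.adj_r2 > ols.adj_r2


class TestLoocv:
    def test_noiseless_linear_is_zero(self, constant_panel):
        panel, _ = constant_panel
        score = h.loocv_score(panel, h.STKernelParams(h=30.0, mu_t=1.0))
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_oracle(self):
        """CV score equals refitting with each observation's weight removed."""
        grid = h.generate_city_grid(10, 50.0, seed=51)
        surf, specs = h.smooth_benchmark(grid, 50.0, noise_sd=0.3)
        df, _ = h.generate_panel(grid, [2018, 2019], surf, specs, seed=52)
        panel = h.CityPanel(df, [s.name for s in specs])
        params = h.STKernelParams(h=40.0, mu_t=25.0)
        X, y = panel.design()
        D2 = _st_distance_matrix(panel, params.lambda_s, params.mu_t)
        total = 0.0
        for i in range(len(y)):
            w = np.exp(-D2[i] / params.h ** 2)
            w[i] = 0.0
            beta = h.fit_local(X, y, w)
            total += (y[i] - X[i] @ beta) ** 2
        assert h.loocv_score(panel, params) == pytest.approx(total, abs=1e-8)

    def test_flat_kernel_equals_ols_press(self, noisy_panel):
        """At huge bandwidth the CV score is the OLS PRESS statistic,
        computed independently from the hat-matrix identity e_i/(1-h_ii)."""
        X, y = noisy_panel.design()
        H = X @ np.linalg.solve(X.T @ X, X.T)
        resid = y - H @ y
        press = float(np.sum((resid / (1.0 - np.diag(H))) ** 2))
        score = h.loocv_score(noisy_panel, h.STKernelParams(h=1e9, mu_t=1.0))
        assert score == pytest.approx(press, rel=1e-6)


class TestBandwidthSelection:
    def test_grid_search_is_argmin(self, noisy_panel):
        grid = [5.0, 10.0, 20.0, 40.0, 80.0]
        h_star, curve = h.select_bandwidth(noisy_panel, 1.0, 10.0, grid=grid)
        scores = dict(curve)
        assert h_star in grid
        assert scores[h_star] == min(scores.values())

    def test_stationary_data_prefers_largest_bandwidth(self, noisy_panel):
        grid = [10.0, 30.0, 100.0, 300.0, 1000.0]
        h_star, curve = h.select_bandwidth(noisy_panel, 1.0, 10.0, grid=grid)
        assert h_star == 1000.0
        scores = [s for _, s in curve]
        assert all(a >= b - 1e-9 for a, b in zip(scores, scores[1:])), \
            "CV curve should decrease toward large h on stationary data"

    def test_golden_section_agrees_with_fine_grid(self, gradient_panel):
        panel, _ = gradient_panel
        mu = h.default_temporal_scale(panel)
        fine = np.linspace(20, 400, 96)
        h_grid, _ = h.select_bandwidth(panel, 1.0, mu, grid=fine)
        tol = 5.0
        h_gold, _ = h.select_bandwidth(panel, 1.0, mu, lo=20, hi=400, tol=tol)
        assert abs(h_gold - h_grid) <= tol

    def test_empty_grid_rejected(self, noisy_panel):
        with pytest.raises(InvalidArgumentError):
            h.select_bandwidth(noisy_panel, 1.0, 1.0, grid=[])


class TestOls:
    def test_exact_line(self):
        x = np.arange(10.0)
        df = _panel_df(x, 2 * x + 1)
        panel = h.CityPanel(df, ["x1"])
        fit = h.fit_ols(panel)
        np.testing.assert_allclose(fit.coefficients, [1.0, 2.0], atol=1e-10)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_matrix_oracle_5x2(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        panel = h.CityPanel(_panel_df(x, y), ["x1"])
        X = np.column_stack([np.ones(5), x])
        expected = np.linalg.inv(X.T @ X) @ X.T @ y
        np.testing.assert_allclose(h.fit_ols(panel).coefficients, expected,
                                   atol=1e-10)

    def test_duplicated_column_rejected(self):
        x = np.arange(10.0)
        df = _panel_df(x, x)
        df["x2"] = df["x1"]
        with pytest.raises(SingularityError, match="x"):
            h.fit_ols(h.CityPanel(df, ["x1", "x2"]))

    def test_standard_errors_positive(self, noisy_panel):
        assert np.all(h.fit_ols(noisy_panel).std_errors > 0)


def _panel_df(x, y):
    import pandas as pd
    n = len(x)
    return pd.DataFrame({"city_id": np.arange(n), "u": np.arange(n, dtype=float),
                         "v": np.zeros(n), "t": 2020, "y": y, "x1": x})
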