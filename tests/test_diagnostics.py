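"""Spatial weights, Moran's I, nonstationarity screen, summary tables."""

import numpy as np
import pandas as pd
import pytest

import hpagtwr as h
from hpagtwr.errors import InvalidArgumentError, UndefinedStatisticError
from hpagtwr.gtwr import GTWRFit, STKernelParams


def lattice_4x4():
    xs, ys = np.meshgrid(np.arange(4.0), np.arange(4.0))
    return np.column_stack([xs.ravel(), ys.ravel()])


def rook_weights_4x4(row_standardize=True):
    """Rook contiguity on the 4x4 unit lattice via inverse distance with
    cutoff equal to the grid step."""
    return h.build_spatial_weights(lattice_4x4(), "inverse_distance",
                                   cutoff=1.0, row_standardize=row_standardize)


def make_fit(coeffs, t=None, names=None):
    """Assemble a GTWRFit around a given local-coefficient matrix."""
    B = np.asarray(coeffs, float)
    n = B.shape[0]
    t = np.full(n, 2020.0) if t is None else np.asarray(t, float)
    names = names or [f"v{j}" for j in range(B.shape[1])]
    z = np.zeros(n)
    return GTWRFit(coefficients=B, fitted=z, residuals=z, hat_diag=z,
                   trace_s=float(B.shape[1]), sigma2=1.0, aicc=0.0,
                   adj_r2=0.0, params=STKernelParams(h=1.0), var_names=names,
                   city_id=np.arange(n), u=z, v=z, t=t)


class TestSpatialWeights:
    def test_two_points_knn_standardized(self):
        W = h.build_spatial_weights(np.array([[0.0, 0], [1, 0]]), "knn", k=1)
        np.testing.assert_allclose(W.w, [[0, 1], [1, 0]])

    def test_row_sums_after_standardization(self):
        pts = np.random.default_rng(1).uniform(0, 10, size=(15, 2))
        W = h.build_spatial_weights(pts, "knn", k=4)
        sums = W.w.sum(axis=1)
        np.testing.assert_allclose(sums[sums > 0], 1.0)

    def test_inverse_distance_cutoff_matches_rook_adjacency(self):
        W = rook_weights_4x4(row_standardize=False)
        # hand-built rook adjacency on the 4x4 lattice
        expected = np.zeros((16, 16))
        for i in range(16):
            xi, yi = i % 4, i // 4
            for j in range(16):
                xj, yj = j % 4, j // 4
                if abs(xi - xj) + abs(yi - yj) == 1:
                    expected[i, j] = 1.0
        np.testing.assert_allclose(W.w, expected)

    def test_knn_symmetrized_by_union(self):
        pts = np.array([[0.0, 0], [1, 0], [10, 0], [10.5, 0]])
        W = h.build_spatial_weights(pts, "knn", k=1, row_standardize=False)
        np.testing.assert_allclose(W.w, W.w.T)

    def test_k_too_large_rejected(self):
        with pytest.raises(InvalidArgumentError):
            h.build_spatial_weights(np.zeros((3, 2)) + np.arange(3)[:, None],
                                    "knn", k=3)


class TestMoransI:
    def test_checkerboard_is_minus_one(self):
        W = rook_weights_4x4()
        vals = np.array([(-1.0) ** ((i % 4) + (i // 4)) for i in range(16)])
        assert h.morans_i(vals, W) == pytest.approx(-1.0, abs=1e-12)
        # direct-summation cross-check of the statistic
        z = vals - vals.mean()
        direct = len(z) / W.s0 * (z @ W.w @ z) / (z @ z)
        assert h.morans_i(vals, W) == pytest.approx(direct)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            h.morans_i(np.ones(16), rook_weights_4x4())

    def test_permutation_null_mean(self):
        """Under random labeling E[I] = -1/(n-1)."""
        W = rook_weights_4x4()
        rng = np.random.default_rng(2)
        vals = rng.normal(size=16)
        sims = [h.morans_i(rng.permutation(vals), W) for _ in range(4000)]
        se = np.std(sims) / np.sqrt(len(sims))
        assert abs(np.mean(sims) - (-1 / 15)) < 4 * se

    def test_eigenvalue_bounds_row_standardized(self):
        W = rook_weights_4x4()
        sym = (W.w + W.w.T) / 2
        n = W.n
        eig = np.linalg.eigvalsh(sym)
        lo, hi = n / W.s0 * eig[0], n / W.s0 * eig[-1]
        rng = np.random.default_rng(3)
        for _ in range(20):
            i_val = h.morans_i(rng.normal(size=n), W)
            assert lo - 1e-9 <= i_val <= hi + 1e-9

    def test_pvalue_determinism_and_floor(self):
        W = rook_weights_4x4()
        vals = np.array([(-1.0) ** ((i % 4) + (i // 4)) for i in range(16)])
        i1, p1 = h.morans_i_pvalue(vals, W, n_perm=999, seed=5,
                                   alternative="two_sided")
        i2, p2 = h.morans_i_pvalue(vals, W, n_perm=999, seed=5,
                                   alternative="two_sided")
        assert (i1, p1) == (i2, p2)
        # floor is 1/(n_perm+1); permutations tying the checkerboard (its
        # +/- values have many equivalent arrangements) may add a count
        assert 1 / 1000 <= p1 <= 5 / 1000

    def test_clustered_surface_significant(self):
        """A radial gradient surface yields p at the permutation floor."""
        grid = h.generate_city_grid(100, 1000.0, seed=61)
        pts = np.column_stack([grid.u, grid.v])
        cu, cv = grid.capital_uv
        vals = np.exp(-np.hypot(grid.u - cu, grid.v - cv) / 300.0)
        W = h.build_spatial_weights(pts, "knn", k=5)
        _, p = h.morans_i_pvalue(vals, W, n_perm=999, seed=62,
                                 alternative="greater")
        assert p <= 0.001

    def test_relabeling_invariance(self):
        """Permutation p is invariant to relabeling cities (exchangeability)."""
        W = rook_weights_4x4()
        rng = np.random.default_rng(7)
        vals = rng.normal(size=16)
        perm = rng.permutation(16)
        W2 = h.SpatialWeightMatrix(W.w[np.ix_(perm, perm)], W.scheme,
                                   W.row_standardized)
        _, p1 = h.morans_i_pvalue(vals, W, n_perm=999, seed=8)
        _, p2 = h.morans_i_pvalue(vals[perm], W2, n_perm=999, seed=8)
        assert p1 == pytest.approx(p2, abs=0.05)


class TestNonstationarity:
    def test_iqr_linear_interpolation(self):
        fit = make_fit(np.arange(1.0, 9.0)[:, None])
        iqr = np.percentile(fit.coefficients[:, 0], 75) - \
            np.percentile(fit.coefficients[:, 0], 25)
        assert iqr == pytest.approx(3.5)

    def test_constant_surfaces_not_flagged(self, constant_panel):
        panel, _ = constant_panel
        fit = h.fit_gtwr(panel, h.STKernelParams(h=30.0, mu_t=1.0))
        ols = h.fit_ols(panel)
        table = h.nonstationarity_test(fit, ols)
        assert table["iqr"].max() < 1e-8
        assert not table["flag"].any()

    def test_gradient_surfaces_flagged(self, gradient_panel):
        from conftest import fit_cv
        panel, _ = gradient_panel
        fit = fit_cv(panel)
        ols = h.fit_ols(panel)
        table = h.nonstationarity_test(fit, ols)
        assert table["flag"].all(), table

    def test_mismatched_variables_rejected(self, constant_panel):
        panel, _ = constant_panel
        fit = h.fit_gtwr(panel, h.STKernelParams(h=30.0, mu_t=1.0))
        ols = h.fit_ols(panel)
        ols.var_names = ["Intercept", "other"]
        with pytest.raises(InvalidArgumentError):
            h.nonstationarity_test(fit, ols)


class TestSummaries:
    def test_constant_coefficients(self):
        fit = make_fit(np.full((10, 2), 3.25))
        table = h.summarize_coefficients(fit)
        assert list(table.columns) == ["AVG", "MIN", "LQ", "MED", "UQ", "MAX"]
        np.testing.assert_allclose(table.to_numpy(), 3.25)

    def test_linear_interpolation_quartiles(self):
        fit = make_fit(np.array([0.0, 1.0, 2.0, 3.0])[:, None])
        row = h.summarize_coefficients(fit).iloc[0]
        assert (row["LQ"], row["MED"], row["UQ"]) == (0.75, 1.5, 2.25)

    def test_ordering_invariant(self, noisy_panel):
        fit = h.fit_gtwr(noisy_panel, h.STKernelParams(h=30.0, mu_t=10.0))
        t = h.summarize_coefficients(fit)
        assert (t["MIN"] <= t["LQ"]).all() and (t["LQ"] <= t["MED"]).all()
        assert (t["MED"] <= t["UQ"]).all() and (t["UQ"] <= t["MAX"]).all()
        assert (t["MIN"] <= t["AVG"]).all() and (t["AVG"] <= t["MAX"]).all()


class TestPeriodAverages:
    def test_change_is_difference(self):
        rng = np.random.default_rng(9)
        B = rng.normal(size=(8, 3))
        t = np.array([2018, 2018, 2019, 2019, 2020, 2020, 2021, 2021])
        table = h.period_average_coefficients(make_fit(B, t=t))
        np.testing.assert_array_equal(
            table["change"].to_numpy(),
            table["during_mean"].to_numpy() - table["before_mean"].to_numpy())
        np.testing.assert_allclose(table["before_mean"], B[:4].mean(axis=0))

    def test_identical_periods_zero_change(self):
        B = np.tile(np.array([1.0, 2.0]), (6, 1))
        t = np.array([2018, 2019, 2019, 2020, 2021, 2021])
        table = h.period_average_coefficients(make_fit(B, t=t))
        np.testing.assert_allclose(table["change"], 0.0)

    def test_empty_period_rejected(self):
        B = np.zeros((4, 1))
        with pytest.raises(InvalidArgumentError):
            h.period_average_coefficients(make_fit(B), split_year=2050)

    def test_step_surface_change_recovered(self):
        """A planted +delta coefficient step at 2020 is recovered by the
        period-average table within 25%."""
        grid = h.generate_city_grid(100, 500.0, seed=71)
        delta = 0.8
        surfaces = h.CoefficientSurfaceSet(
            intercept=h.constant_surface(1.0),
            slopes={"x1": h.step_surface(1.0, delta, year=2020)},
            noise_sd=0.05)
        specs = [h.CovariateSpec("x1", 0.0, 1.0, -4.0, 4.0)]
        df, _ = h.generate_panel(grid, [2018, 2019, 2020, 2021], surfaces,
                                 specs, seed=72)
        panel = h.CityPanel(df, ["x1"])
        # temporally weighted scale: a purely temporal shift needs years to
        # separate more strongly than one spatial neighbour hop
        mu = 9.0 * h.default_temporal_scale(panel)
        h_star, _ = h.select_bandwidth(panel, 1.0, mu,
                                       grid=np.geomspace(10, 2000, 20))
        fit = h.fit_gtwr(panel, h.STKernelParams(h=h_star, mu_t=mu))
        est = h.period_average_coefficients(fit).loc["x1", "change"]
        assert abs(est - delta) <= 0.25 * delta
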