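import numpy as np
import pytest

import hpagtwr as h


@pytest.fixture(scope="session")
def small_grid():
    return h.generate_city_grid(20, 100.0, seed=101)


@pytest.fixture(scope="session")
def constant_panel(small_grid):
    """Zero-noise panel with constant coefficients: y = 1 + 2*x1 exactly."""
    surfaces = h.CoefficientSurfaceSet(
        intercept=h.constant_surface(1.0),
        slopes={"x1": h.constant_surface(2.0)},
        noise_sd=0.0,
    )
    specs = [h.CovariateSpec("x1", 0.0, 1.0, -4.0, 4.0)]
    df, truth = h.generate_panel(small_grid, [2018, 2019, 2020, 2021],
                                 surfaces, specs, seed=102)
    return h.CityPanel(df, ["x1"]), truth


@pytest.fixture(scope="session")
def noisy_panel(small_grid):
    """Constant-coefficient panel with noise (stationary data)."""
    surfaces = h.CoefficientSurfaceSet(
        intercept=h.constant_surface(1.0),
        slopes={"x1": h.constant_surface(2.0), "x2": h.constant_surface(-1.0)},
        noise_sd=0.5,
    )
    specs = [h.CovariateSpec(n, 0.0, 1.0, -4.0, 4.0) for n in ("x1", "x2")]
    df, _ = h.generate_panel(small_grid, [2018, 2019, 2020, 2021],
                             surfaces, specs, seed=103)
    return h.CityPanel(df, ["x1", "x2"])


@pytest.fixture(scope="session")
def gradient_panel():
    """Smooth strongly varying coefficient surfaces with small noise."""
    grid = h.generate_city_grid(80, 1000.0, seed=104)
    surfaces, specs = h.smooth_benchmark(grid, 1000.0, noise_sd=0.1)
    df, truth = h.generate_panel(grid, [2018, 2019, 2020, 2021],
                                 surfaces, specs, seed=105)
    return h.CityPanel(df, [s.name for s in specs]), truth


def fit_cv(panel, lambda_s=1.0, mu_t=None):
    """Convenience: CV-select a bandwidth and fit."""
    if mu_t is None:
        mu_t = h.default_temporal_scale(panel)
    from hpagtwr.gtwr import _st_distance_matrix
    d2 = _st_distance_matrix(panel, lambda_s, mu_t)
    dmax = float(np.sqrt(d2.max()))
    h_star, _ = h.select_bandwidth(panel, lambda_s, mu_t, lo=dmax / 100,
                                   hi=2 * dmax, tol=dmax / 200)
    return h.fit_gtwr(panel, h.STKernelParams(h=h_star, lambda_s=lambda_s,
                                              mu_t=mu_t))
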