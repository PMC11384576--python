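"""Fit GTWR with CV bandwidth selection and compare against OLS.

Uses the three-covariate smooth-surface benchmark at the study scale
(323 cities x 4 years), selects the bandwidth by leave-one-out CV, and
reports coefficient-surface recovery, model comparison, and the standard
diagnostic tables.
"""

import numpy as np

import hpagtwr as h
from hpagtwr.gtwr import _st_distance_matrix

grid = h.generate_city_grid(323, 1000.0, seed=11)
surfaces, specs = h.smooth_benchmark(grid, 1000.0, noise_sd=0.25)
df, truth = h.generate_panel(grid, [2018, 2019, 2020, 2021], surfaces,
                             specs, seed=12)
panel = h.CityPanel(df, [s.name for s in specs])

mu = h.default_temporal_scale(panel)
d2 = _st_distance_matrix(panel, 1.0, mu)
dmax = float(np.sqrt(d2.max()))
h_star, cv_curve = h.select_bandwidth(panel, 1.0, mu, lo=dmax / 100,
                                      hi=2 * dmax, tol=dmax / 200)
fit = h.fit_gtwr(panel, h.STKernelParams(h=h_star, mu_t=mu))
ols = h.fit_ols(panel)

print(f"CV-selected bandwidth h* = {h_star:.1f} km-equivalent "
      f"({len(cv_curve)} CV evaluations, mu_t = {mu:.0f})")
print(f"GTWR: AICc = {fit.aicc:.2f}, adj R^2 = {fit.adj_r2:.4f}, "
      f"trace(S) = {fit.trace_s:.1f}")
print(f"OLS : AICc = {ols.aicc:.2f}, adj R^2 = {ols.adj_r2:.4f}")

print("\ncoefficient-surface recovery (Pearson r vs generator truth):")
for j, name in enumerate(truth.columns):
    r = np.corrcoef(fit.coefficients[:, j], truth.iloc[:, j])[0, 1]
    print(f"  {name:10s} r = {r:.3f}")

print("\nlocal-coefficient summary (quantiles over all observations):")
print(h.summarize_coefficients(fit).round(3).to_string())
print("\nnonstationarity screen (IQR of local coefficients vs 2x OLS SE):")
print(h.nonstationarity_test(fit, ols).round(4).to_string())
# GTWR should beat OLS on both criteria and flag every variable whose
# surface truly varies; recovery r near 1 means the local estimates track
# the planted surfaces.
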