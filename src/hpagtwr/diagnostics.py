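"""Pre- and post-fit diagnostics for the spatiotemporal regression.

Covers global Moran's I with permutation inference (justifying a spatial
model before fitting), the spatial-nonstationarity screen (interquartile
range of local coefficients vs twice the OLS standard error), and the two
standard reporting tables: per-variable quantile summaries of local
coefficients and period-averaged coefficients around a split year
(default 2020, the pandemic onset).

Quantiles throughout use linear interpolation (the type-7 convention,
numpy's default), stated explicitly so table values are exactly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .errors import InvalidArgumentError, UndefinedStatisticError
from .gtwr import GTWRFit, OLSFit

__all__ = [
    "SpatialWeightMatrix",
    "DiagnosticsReport",
    "build_spatial_weights",
    "morans_i",
    "morans_i_pvalue",
    "nonstationarity_test",
    "summarize_coefficients",
    "period_average_coefficients",
]


# --------------------------------------------------------------------------
# spatial weights
# --------------------------------------------------------------------------


@dataclass
class SpatialWeightMatrix:
    """Dense n-by-n nonnegative spatial weights with zero diagonal."""

    w: np.ndarray
    scheme: str
    row_standardized: bool

    def __post_init__(self):
        w = np.asarray(self.w, float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InvalidArgumentError("weight matrix must be square")
        if np.any(w < 0):
            raise InvalidArgumentError("weights must be non-negative")
        if np.any(np.diagonal(w) != 0):
            raise InvalidArgumentError("diagonal must be zero")
        if self.row_standardized:
            sums = w.sum(axis=1)
            nz = sums > 0
            if not np.allclose(sums[nz], 1.0):
                raise InvalidArgumentError(
                    "row-standardized rows must sum to 1")
        self.w = w

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def s0(self) -> float:
        return float(self.w.sum())


def build_spatial_weights(
    points: np.ndarray,
    scheme: str = "knn",
    *,
    k: int = 5,
    cutoff: float | None = None,
    row_standardize: bool = True,
) -> SpatialWeightMatrix:
    """Build spatial weights from unique-city coordinates.

    ``scheme="knn"``: binary k-nearest-neighbour weights symmetrized by
    union (i~j if either is among the other's k nearest).
    ``scheme="inverse_distance"``: w_ij = 1/d_ij for d_ij <= cutoff, else 0
    (symmetric by construction). Row standardization rescales each nonzero
    row to sum to one.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise InvalidArgumentError("need >= 2 points with 2-D coordinates")
    n = pts.shape[0]
    if len(np.unique(pts, axis=0)) != n:
        raise InvalidArgumentError("points must be distinct")

    if scheme == "knn":
        if k >= n:
            raise InvalidArgumentError(f"k={k} must be < number of points {n}")
        tree = cKDTree(pts)
        _, idx = tree.query(pts, k=k + 1)  # first neighbour is self
        w = np.zeros((n, n))
        rows = np.repeat(np.arange(n), k)
        w[rows, idx[:, 1:].ravel()] = 1.0
        w = np.maximum(w, w.T)  # union symmetrization
    elif scheme == "inverse_distance":
        if cutoff is None or cutoff <= 0:
            raise InvalidArgumentError("inverse_distance needs a positive cutoff")
        d = squareform(pdist(pts))
        with np.errstate(divide="ignore"):
            w = np.where((d > 0) & (d <= cutoff), 1.0 / np.where(d > 0, d, 1.0), 0.0)
        np.fill_diagonal(w, 0.0)
    else:
        raise InvalidArgumentError(f"unknown scheme {scheme!r}")

    if row_standardize:
        sums = w.sum(axis=1, keepdims=True)
        w = np.divide(w, sums, out=np.zeros_like(w), where=sums > 0)
    return SpatialWeightMatrix(w=w, scheme=scheme,
                               row_standardized=row_standardize)


# --------------------------------------------------------------------------
# Moran's I
# --------------------------------------------------------------------------


def morans_i(values: Sequence[float], W: SpatialWeightMatrix) -> float:
    """Global Moran's I: (n/S0) * sum_ij w_ij z_i z_j / sum_i z_i^2."""
    z = np.asarray(values, float)
    if len(z) != W.n:
        raise InvalidArgumentError("values length must match weight matrix")
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise UndefinedStatisticError(
            "Moran's I undefined for a constant vector (zero variance)")
    return float(len(z) / W.s0 * (z @ W.w @ z) / denom)


def morans_i_pvalue(
    values: Sequence[float],
    W: SpatialWeightMatrix,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Permutation p-value for Moran's I.

    p = (1 + #{permuted |as or more extreme|}) / (1 + n_perm); the smallest
    attainable p is therefore 1/(n_perm+1). Returns ``(I_observed, p)``.
    """
    if n_perm < 99:
        raise InvalidArgumentError("n_perm must be >= 99")
    if alternative not in ("greater", "two_sided"):
        raise InvalidArgumentError("alternative must be 'greater' or 'two_sided'")
    obs = morans_i(values, W)
    rng = np.random.default_rng(seed)
    vals = np.asarray(values, float)
    perm = np.empty(n_perm)
    for b in range(n_perm):
        perm[b] = morans_i(rng.permutation(vals), W)
    if alternative == "greater":
        extreme = int((perm >= obs).sum())
    else:
        e_i = -1.0 / (len(vals) - 1)  # null expectation
        extreme = int((np.abs(perm - e_i) >= abs(obs - e_i)).sum())
    return obs, (1 + extreme) / (1 + n_perm)


# --------------------------------------------------------------------------
# nonstationarity and summary tables
# --------------------------------------------------------------------------


def nonstationarity_test(gtwr: GTWRFit, ols: OLSFit) -> pd.DataFrame:
    """Per-variable spatial-nonstationarity screen.

    A variable shows meaningful local variation when the interquartile range
    of its local coefficients exceeds twice the OLS standard error of the
    corresponding global coefficient. Columns: iqr, two_se, flag.
    """
    if gtwr.var_names != ols.var_names:
        raise InvalidArgumentError("fits must share the same covariate ordering")
    q1, q3 = np.percentile(gtwr.coefficients, [25, 75], axis=0)
    iqr = q3 - q1
    two_se = 2.0 * ols.std_errors
    # absolute floor keeps exactly-fit (zero-SE, zero-IQR) designs unflagged
    flag = iqr > two_se + 1e-10
    return pd.DataFrame({"iqr": iqr, "two_se": two_se, "flag": flag},
                        index=pd.Index(gtwr.var_names, name="variable"))


def summarize_coefficients(gtwr: GTWRFit) -> pd.DataFrame:
    """Quantile summary of local coefficients per variable.

    Columns AVG/MIN/LQ/MED/UQ/MAX: mean, minimum, quartiles (linear
    interpolation) and maximum over the n local coefficient values.
    """
    if gtwr.n < 4:
        raise InvalidArgumentError("need >= 4 observations to summarize")
    B = gtwr.coefficients
    lq, med, uq = np.percentile(B, [25, 50, 75], axis=0)
    return pd.DataFrame(
        {"AVG": B.mean(axis=0), "MIN": B.min(axis=0), "LQ": lq,
         "MED": med, "UQ": uq, "MAX": B.max(axis=0)},
        index=pd.Index(gtwr.var_names, name="variable"))


def period_average_coefficients(gtwr: GTWRFit, split_year: int = 2020
                                ) -> pd.DataFrame:
    """Mean local coefficients before (t < split) and during (t >= split)
    a split year, plus the change (during - before)."""
    before = gtwr.t < split_year
    during = ~before
    if not before.any() or not during.any():
        raise InvalidArgumentError(
            f"split year {split_year} leaves an empty period")
    b = gtwr.coefficients[before].mean(axis=0)
    d = gtwr.coefficients[during].mean(axis=0)
    return pd.DataFrame(
        {"before_mean": b, "during_mean": d, "change": d - b},
        index=pd.Index(gtwr.var_names, name="variable"))


# --------------------------------------------------------------------------
# report container
# --------------------------------------------------------------------------


@dataclass
class DiagnosticsReport:
    """Bundle of all diagnostics, serializable to JSON/CSV."""

    morans_i: float
    morans_p: float
    n_perm: int
    seed: int
    nonstationarity: pd.DataFrame
    coefficient_summary: pd.DataFrame
    period_averages: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "morans_i": {"statistic": self.morans_i, "p_value": self.morans_p,
                         "n_perm": self.n_perm, "seed": self.seed},
            "nonstationarity": self.nonstationarity.reset_index()
                                   .to_dict(orient="records"),
            "coefficient_summary": self.coefficient_summary.reset_index()
                                       .to_dict(orient="records"),
            "period_averages": self.period_averages.reset_index()
                                   .to_dict(orient="records"),
        }
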