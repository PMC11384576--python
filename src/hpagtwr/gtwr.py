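"""Geographically and temporally weighted regression (GTWR).

The model lets every regression coefficient vary over space and time:

    y_i = beta_0(u_i, v_i, t_i) + sum_k beta_k(u_i, v_i, t_i) x_ik + eps_i.

At each observation i a weighted least-squares fit is solved with kernel
weights on the squared spacetime distance

    d2_ST(i, j) = lambda_s * [(u_i-u_j)^2 + (v_i-v_j)^2] + mu_t * (t_i-t_j)^2,

an additive combination of spatial and temporal separation with scale
weights lambda_s and mu_t. The kernel bandwidth h is selected by
leave-one-out cross-validation (the focal observation's weight is zeroed).
Fit quality is summarized by the hat-matrix trace (effective number of
parameters), the GWR-convention corrected AIC, and adjusted R^2; an OLS
baseline with the same AICc convention supports model comparison and the
spatial-nonstationarity test in :mod:`hpagtwr.diagnostics`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr
from scipy.spatial.distance import pdist, squareform

from .errors import BandwidthError, InvalidArgumentError, SingularityError

__all__ = [
    "ObservationPoint",
    "CityPanel",
    "STKernelParams",
    "GTWRFit",
    "OLSFit",
    "st_distance_sq",
    "kernel_weight",
    "fit_local",
    "fit_gtwr",
    "loocv_score",
    "select_bandwidth",
    "default_temporal_scale",
    "fit_ols",
]

logger = logging.getLogger(__name__)

#: reciprocal-condition threshold below which a local design is treated as
#: singular
RCOND_TOL = 1e-10


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ObservationPoint:
    """A single observation: location, year, response, covariates."""

    city_id: int
    u: float
    v: float
    t: float
    y: float = math.nan
    x: tuple[float, ...] = ()


@dataclass
class CityPanel:
    """A city-by-year panel ready for regression.

    ``data`` holds columns ``city_id, u, v, t, y`` plus the covariates named
    in ``covariates``; the intercept is implicit and always included in the
    design matrix.
    """

    data: pd.DataFrame
    covariates: list[str]

    REQUIRED = ("city_id", "u", "v", "t", "y")

    def __post_init__(self):
        missing = [c for c in (*self.REQUIRED, *self.covariates)
                   if c not in self.data.columns]
        if missing:
            raise InvalidArgumentError(f"panel missing columns: {missing}")
        if self.data.duplicated(["city_id", "t"]).any():
            raise InvalidArgumentError("(city_id, t) keys must be unique")
        core = self.data[["u", "v", "y", *self.covariates]].to_numpy(float)
        if not np.all(np.isfinite(core)):
            raise InvalidArgumentError("panel contains non-finite values")
        if len(self.data) <= len(self.covariates) + 1:
            raise InvalidArgumentError(
                "panel needs more observations than parameters")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def var_names(self) -> list[str]:
        """Design-matrix column names, intercept first."""
        return ["Intercept", *self.covariates]

    def design(self) -> tuple[np.ndarray, np.ndarray]:
        """(X with leading intercept column, y)."""
        n = len(self.data)
        X = np.column_stack(
            [np.ones(n)] + [self.data[c].to_numpy(float) for c in self.covariates])
        return X, self.data["y"].to_numpy(float)

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.data["u"].to_numpy(float),
                self.data["v"].to_numpy(float),
                self.data["t"].to_numpy(float))


@dataclass(frozen=True)
class STKernelParams:
    """Kernel family, bandwidth, and spacetime scale weights."""

    h: float
    lambda_s: float = 1.0
    mu_t: float = 1.0
    kernel: str = "gaussian"

    def __post_init__(self):
        if self.h <= 0:
            raise InvalidArgumentError("bandwidth h must be > 0")
        if self.lambda_s < 0 or self.mu_t < 0 or self.lambda_s + self.mu_t == 0:
            raise InvalidArgumentError(
                "lambda_s, mu_t must be >= 0 and not both zero")
        if self.kernel not in ("gaussian", "bisquare"):
            raise InvalidArgumentError(f"unknown kernel {self.kernel!r}")


@dataclass
class GTWRFit:
    """Per-observation local coefficients and fit statistics."""

    coefficients: np.ndarray  # (n, k+1), intercept first
    fitted: np.ndarray
    residuals: np.ndarray
    hat_diag: np.ndarray
    trace_s: float
    sigma2: float
    aicc: float
    adj_r2: float
    params: STKernelParams
    var_names: list[str]
    city_id: np.ndarray
    u: np.ndarray
    v: np.ndarray
    t: np.ndarray

    @property
    def n(self) -> int:
        return len(self.fitted)

    def local_table(self) -> pd.DataFrame:
        """Local coefficients as a tidy frame (one row per observation)."""
        out = pd.DataFrame({"city_id": self.city_id, "t": self.t,
                            "u": self.u, "v": self.v})
        for j, name in enumerate(self.var_names):
            out[f"beta_{name}"] = self.coefficients[:, j]
        out["hat_ii"] = self.hat_diag
        return out

    def summary_dict(self) -> dict:
        return {"aicc": self.aicc, "adj_r2": self.adj_r2,
                "trace_s": self.trace_s, "sigma2": self.sigma2,
                "h": self.params.h, "lambda_s": self.params.lambda_s,
                "mu_t": self.params.mu_t, "kernel": self.params.kernel,
                "n": self.n}


@dataclass
class OLSFit:
    """Global least-squares baseline with GWR-convention AICc."""

    coefficients: np.ndarray
    std_errors: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    aicc: float
    adj_r2: float
    var_names: list[str]

    @property
    def n(self) -> int:
        return len(self.fitted)


# --------------------------------------------------------------------------
# kernels and distances
# --------------------------------------------------------------------------


def st_distance_sq(i, j, lambda_s: float, mu_t: float) -> float:
    """Squared spacetime distance lambda_s*d2_space + mu_t*d2_time."""
    if lambda_s < 0 or mu_t < 0 or lambda_s + mu_t == 0:
        raise InvalidArgumentError(
            "lambda_s, mu_t must be >= 0 and not both zero")
    d2s = (i.u - j.u) ** 2 + (i.v - j.v) ** 2
    d2t = (i.t - j.t) ** 2
    return lambda_s * d2s + mu_t * d2t


def kernel_weight(d2, h: float, family: str = "gaussian"):
    """Kernel weight for squared distance ``d2`` at bandwidth ``h``.

    gaussian: exp(-d2/h^2); bisquare: (1 - d2/h^2)^2 for d2 < h^2, else 0.
    """
    if h <= 0:
        raise InvalidArgumentError("bandwidth h must be > 0")
    d2 = np.asarray(d2, dtype=float)
    if np.any(d2 < 0):
        raise InvalidArgumentError("squared distance must be >= 0")
    if family == "gaussian":
        out = np.exp(-d2 / (h * h))
    elif family == "bisquare":
        out = np.where(d2 < h * h, (1.0 - d2 / (h * h)) ** 2, 0.0)
    else:
        raise InvalidArgumentError(f"unknown kernel {family!r}")
    return out if out.ndim else float(out)


def _st_distance_matrix(panel: CityPanel, lambda_s: float, mu_t: float
                        ) -> np.ndarray:
    """(n, n) combined squared spacetime distances.

    Years are centered before squaring; pairwise differences are unaffected,
    but centering keeps intermediate magnitudes small.
    """
    u, v, t = panel.coords()
    t = t - t.mean()
    d2s = squareform(pdist(np.column_stack([u, v]), "sqeuclidean"))
    d2t = (t[:, None] - t[None, :]) ** 2
    return lambda_s * d2s + mu_t * d2t


def default_temporal_scale(panel: CityPanel) -> float:
    """Default mu_t = tau^2 with tau = median nearest-neighbour spatial
    distance between distinct cities, so one year of separation weighs like
    a typical inter-city hop."""
    pts = panel.data.drop_duplicates("city_id")[["u", "v"]].to_numpy(float)
    d = squareform(pdist(pts))
    np.fill_diagonal(d, np.inf)
    tau = float(np.median(d.min(axis=1)))
    return tau * tau


# --------------------------------------------------------------------------
# local and global fitting
# --------------------------------------------------------------------------


def fit_local(X: np.ndarray, y: np.ndarray, w: np.ndarray,
              focal: int | None = None) -> np.ndarray:
    """Solve the weighted least-squares problem (X'WX)b = X'Wy.

    Solved via QR on the sqrt(w)-scaled system for numerical stability.
    Raises :class:`SingularityError` when the weighted design is
    rank-deficient or its reciprocal condition falls below ``RCOND_TOL``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if np.any(w < 0):
        raise InvalidArgumentError("weights must be non-negative")
    p = X.shape[1]
    if np.count_nonzero(w) < p:
        raise SingularityError(
            f"fewer than {p} observations with positive weight", focal=focal)
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    sv = np.linalg.svd(Xw, compute_uv=False)
    if sv[0] == 0 or (sv[-1] / sv[0]) ** 2 < RCOND_TOL:
        raise SingularityError(
            "weighted design is singular or near-singular"
            + (f" at focal observation {focal}" if focal is not None else ""),
            focal=focal)
    beta, *_ = np.linalg.lstsq(Xw, y * sw, rcond=None)
    return beta


def _batched_local_solve(X: np.ndarray, y: np.ndarray, W: np.ndarray,
                         check: bool = True) -> np.ndarray:
    """Local coefficients for every focal row of weight matrix W (n, n).

    Returns (n, p). With ``check`` the batched normal matrices are screened
    for near-singularity (reciprocal condition < RCOND_TOL) and the first
    offending focal index is reported.
    """
    A = np.einsum("fn,nj,nk->fjk", W, X, X, optimize=True)  # X' W_f X
    b = W @ (X * y[:, None])  # X' W_f y
    if check:
        eig = np.linalg.eigvalsh(A)
        rcond = eig[:, 0] / np.maximum(eig[:, -1], np.finfo(float).tiny)
        bad = np.where(~(rcond > RCOND_TOL))[0]
        if len(bad):
            raise SingularityError(
                f"near-singular local design at focal observation {bad[0]} "
                f"(rcond={rcond[bad[0]]:.2e})", focal=int(bad[0]))
    return np.linalg.solve(A, b[:, :, None])[:, :, 0]


def _gwr_aicc(n: int, rss: float, trace_s: float) -> float:
    """Corrected AIC in the GWR convention with trace(S) effective params."""
    sigma2 = max(rss / n, np.finfo(float).tiny)  # guard exact fits
    return (n * math.log(sigma2) + n * math.log(2 * math.pi)
            + n * (n + trace_s) / (n - 2 - trace_s))


def fit_gtwr(panel: CityPanel, params: STKernelParams) -> GTWRFit:
    """Fit the full GTWR model at every observation of the panel."""
    X, y = panel.design()
    n, p = X.shape
    D2 = _st_distance_matrix(panel, params.lambda_s, params.mu_t)
    W = kernel_weight(D2, params.h, params.kernel)

    beta = _batched_local_solve(X, y, W)
    fitted = np.einsum("ij,ij->i", X, beta)
    residuals = y - fitted

    # hat diagonal: s_ii = w_ii * x_i' (X'W_iX)^{-1} x_i
    A = np.einsum("fn,nj,nk->fjk", W, X, X, optimize=True)
    z = np.linalg.solve(A, X[:, :, None])[:, :, 0]
    hat_diag = np.diagonal(W) * np.einsum("ij,ij->i", X, z)

    trace_s = float(hat_diag.sum())
    if trace_s >= n - 2:
        raise BandwidthError(
            f"bandwidth h={params.h} too small: trace(S)={trace_s:.2f} >= n-2={n - 2}")
    rss = float(residuals @ residuals)
    tss = float(((y - y.mean()) ** 2).sum())
    sigma2 = rss / n
    aicc = _gwr_aicc(n, rss, trace_s)
    adj_r2 = 1.0 - (rss / (n - trace_s)) / (tss / (n - 1)) if tss > 0 else math.nan

    u, v, t = panel.coords()
    return GTWRFit(
        coefficients=beta, fitted=fitted, residuals=residuals,
        hat_diag=hat_diag, trace_s=trace_s, sigma2=sigma2, aicc=aicc,
        adj_r2=adj_r2, params=params, var_names=panel.var_names,
        city_id=panel.data["city_id"].to_numpy(), u=u, v=v, t=t)


def loocv_score(panel: CityPanel, params: STKernelParams) -> float:
    """Leave-one-out CV score: sum of squared prediction errors with each
    focal observation's own weight zeroed.

    A singular local fit yields ``+inf`` (logged) so bandwidth search can
    continue past degenerate candidates.
    """
    X, y = panel.design()
    D2 = _st_distance_matrix(panel, params.lambda_s, params.mu_t)
    return _loocv_from_distance(X, y, D2, params.h, params.kernel)


def _loocv_from_distance(X, y, D2, h, kernel) -> float:
    W = kernel_weight(D2, h, kernel)
    np.fill_diagonal(W, 0.0)
    try:
        beta = _batched_local_solve(X, y, W)
    except SingularityError as exc:
        logger.warning("LOOCV at h=%g: %s; score set to +inf", h, exc)
        return math.inf
    yhat = np.einsum("ij,ij->i", X, beta)
    return float(((y - yhat) ** 2).sum())


_GOLDEN = (math.sqrt(5) - 1) / 2


def select_bandwidth(
    panel: CityPanel,
    lambda_s: float = 1.0,
    mu_t: float | None = None,
    *,
    grid: Sequence[float] | None = None,
    lo: float | None = None,
    hi: float | None = None,
    tol: float = 1e-2,
    kernel: str = "gaussian",
) -> tuple[float, list[tuple[float, float]]]:
    """Select the CV-optimal bandwidth h*.

    Either ``grid`` (explicit candidate list) or ``(lo, hi, tol)`` for a
    golden-section search on an assumed-unimodal CV curve must be given.
    Returns ``(h_star, cv_curve)`` where cv_curve lists every evaluated
    ``(h, score)``. Ties break toward the larger h (the smoother model).
    """
    if mu_t is None:
        mu_t = default_temporal_scale(panel)
    X, y = panel.design()
    D2 = _st_distance_matrix(panel, lambda_s, mu_t)
    cache: dict[float, float] = {}

    def cv(h: float) -> float:
        if h not in cache:
            cache[h] = _loocv_from_distance(X, y, D2, h, kernel)
        return cache[h]

    if grid is not None:
        if len(grid) == 0:
            raise InvalidArgumentError("bandwidth grid must be non-empty")
        curve = [(float(h), cv(float(h))) for h in grid]
        finite = [(h, s) for h, s in curve if math.isfinite(s)]
        if not finite:
            raise BandwidthError("no candidate bandwidth gave a finite CV score")
        best = min(finite, key=lambda hs: (hs[1], -hs[0]))
        return best[0], curve

    if lo is None or hi is None or not lo < hi:
        raise InvalidArgumentError("need grid, or lo < hi for golden section")
    a, b = float(lo), float(hi)
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    while b - a > tol:
        if cv(c) < cv(d):  # tie -> keep the larger-h side
            b = d
        else:
            a = c
        c = b - _GOLDEN * (b - a)
        d = a + _GOLDEN * (b - a)
    h_star = (a + b) / 2
    score = cv(h_star)
    curve = sorted(cache.items())
    if not math.isfinite(score):
        finite = [(h, s) for h, s in curve if math.isfinite(s)]
        if not finite:
            raise BandwidthError("no candidate bandwidth gave a finite CV score")
        h_star = min(finite, key=lambda hs: (hs[1], -hs[0]))[0]
    return float(h_star), [(float(h), float(s)) for h, s in curve]


def fit_ols(panel: CityPanel) -> OLSFit:
    """Global OLS baseline with the same AICc convention as the GTWR fit
    (effective parameters p = k+1), so the two criteria are comparable."""
    X, y = panel.design()
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        _, _, piv = qr(X, pivoting=True)
        collinear = sorted(panel.var_names[j] for j in piv[rank:])
        raise SingularityError(
            f"rank-deficient design: collinear columns {collinear}")
    res = sm.OLS(y, X).fit()
    rss = float(res.resid @ res.resid)
    return OLSFit(
        coefficients=np.asarray(res.params),
        std_errors=np.asarray(res.bse),
        fitted=np.asarray(res.fittedvalues),
        residuals=np.asarray(res.resid),
        aicc=_gwr_aicc(n, rss, float(p)),
        adj_r2=float(res.rsquared_adj),
        var_names=panel.var_names)
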