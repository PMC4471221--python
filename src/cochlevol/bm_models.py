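"""Brownian-motion likelihoods, Pagel's-lambda signal tests, model comparison.

Under Brownian motion a continuous trait observed at the tips of a rooted
phylogram is multivariate normal with mean ``alpha * 1`` and covariance
``sigma2 * V_lambda``, where V is the shared-path-length matrix and lambda
rescales its off-diagonals.  Everything here uses ML (not REML) estimators,
matching the likelihood-ratio testing framework.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg, optimize, stats

from .errors import (
    ConvergenceError,
    DegenerateDataError,
    IdentifiabilityError,
    InvalidParameterError,
)
from .treeio import PhyloCovariance, lambda_transform, tip_depths, vcv_from_tree

__all__ = [
    "BrownianFit",
    "SignalTestResult",
    "bm_loglik",
    "gls_profile",
    "fit_brownian",
    "fit_directional",
    "lr_test",
    "lambda_signal_test",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class BrownianFit:
    """A fitted (lambda-scaled) Brownian trait-evolution model."""

    alpha: float                 # phylogenetically weighted root mean
    sigma2: float                # Brownian variance per unit branch length
    lam: Optional[float]         # Pagel's lambda (None when profile is flat)
    loglik: float
    n_params: int                # evolutionary parameters (BM: 1, drift: 2)
    beta: Optional[float] = None # directional drift per unit path length
    profile_flat: bool = False   # lambda likelihood profile carried no signal
    degenerate: bool = False     # trait constant across tips


@dataclass(frozen=True)
class SignalTestResult:
    """Four-step Pagel's-lambda signal test result for one trait."""

    lambda_ml: Optional[float]
    loglik_ml: float
    loglik_lambda0: float
    loglik_lambda1: float
    p_vs_0: float
    p_vs_1: float
    degenerate: bool = False


def _chol(V: np.ndarray):
    try:
        return linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance matrix is singular; check for zero terminal branches "
            "or duplicated tips"
        ) from exc


def bm_loglik(y: np.ndarray, V: PhyloCovariance | np.ndarray,
              alpha: float, sigma2: float) -> float:
    """Log density of tip data under N(alpha * 1, sigma2 * V)."""
    Vm = V.matrix if isinstance(V, PhyloCovariance) else np.asarray(V, float)
    y = np.asarray(y, float)
    n = y.shape[0]
    if sigma2 <= 0:
        raise InvalidParameterError("sigma2 must be > 0")
    c = _chol(Vm)
    r = y - alpha
    solve = linalg.cho_solve(c, r)
    quad = float(r @ solve)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    return -0.5 * (n * _LOG2PI + n * math.log(sigma2) + logdet + quad / sigma2)


def gls_profile(y: np.ndarray, Vm: np.ndarray, X: Optional[np.ndarray] = None):
    """Profile out GLS coefficients and the ML error variance.

    Returns ``(beta_hat, sigma2_hat, loglik)`` for the model
    ``y ~ N(X b, sigma2 * Vm)``; ``X`` defaults to the intercept column.
    """
    y = np.asarray(y, float)
    n = y.shape[0]
    if X is None:
        X = np.ones((n, 1))
    c = _chol(Vm)
    Vi_X = linalg.cho_solve(c, X)
    Vi_y = linalg.cho_solve(c, y)
    xtvx = X.T @ Vi_X
    beta = np.linalg.solve(xtvx, X.T @ Vi_y)
    r = y - X @ beta
    quad = float(r @ linalg.cho_solve(c, r))
    sigma2 = quad / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    if sigma2 <= 0:
        loglik = math.inf  # degenerate perfect fit
    else:
        loglik = -0.5 * (n * _LOG2PI + n * math.log(sigma2) + logdet + n)
    return beta, sigma2, loglik


def _profile_loglik_lambda(y, V: PhyloCovariance, lam: float,
                           X: Optional[np.ndarray] = None) -> float:
    Vl = lambda_transform(V, lam)
    return gls_profile(y, Vl.matrix, X)[2]


def fit_brownian(
    y: np.ndarray,
    tree_or_V,
    lam_mode="ml",
    grid_size: int = 21,
) -> BrownianFit:
    """Fit (lambda-scaled) Brownian motion by maximum likelihood.

    ``lam_mode`` is ``"ml"`` to profile lambda over [0, 1] or a fixed float.
    The profile is scanned on a coarse grid and refined by bounded scalar
    optimization; a flat profile (e.g. star tree) is flagged rather than
    returning an arbitrary lambda.
    """
    y = np.asarray(y, float)
    if y.shape[0] < 3:
        raise InvalidParameterError("need at least 3 tips")
    V = tree_or_V if isinstance(tree_or_V, PhyloCovariance) else vcv_from_tree(tree_or_V)
    if np.ptp(y) == 0.0:
        return BrownianFit(alpha=float(y[0]), sigma2=0.0, lam=None,
                           loglik=math.inf, n_params=1, degenerate=True)

    def fit_at(lam: float):
        Vl = lambda_transform(V, lam)
        beta, sigma2, ll = gls_profile(y, Vl.matrix)
        return float(beta[0]), sigma2, ll

    if lam_mode != "ml":
        lam = float(lam_mode)
        if not (0.0 <= lam <= 1.0):
            raise InvalidParameterError("fixed lambda must be in [0, 1]")
        alpha, sigma2, ll = fit_at(lam)
        return BrownianFit(alpha=alpha, sigma2=sigma2, lam=lam, loglik=ll,
                           n_params=1)

    grid = np.linspace(0.0, 1.0, grid_size)
    lls = np.array([_profile_loglik_lambda(y, V, l) for l in grid])
    if not np.all(np.isfinite(lls)):
        raise ConvergenceError("non-finite profile log-likelihood",
                               profile=list(zip(grid, lls)))
    if np.ptp(lls) < 1e-8:
        alpha, sigma2, ll = fit_at(1.0)
        return BrownianFit(alpha=alpha, sigma2=sigma2, lam=None, loglik=ll,
                           n_params=1, profile_flat=True)
    k = int(np.argmax(lls))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid_size - 1)]
    res = optimize.minimize_scalar(
        lambda l: -_profile_loglik_lambda(y, V, l),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-7},
    )
    candidates = [(float(res.x), -float(res.fun))] + list(zip(grid, lls))
    lam_hat, ll_hat = max(candidates, key=lambda t: t[1])
    alpha, sigma2, _ = fit_at(lam_hat)
    return BrownianFit(alpha=alpha, sigma2=sigma2, lam=lam_hat, loglik=ll_hat,
                       n_params=1)


def fit_directional(y: np.ndarray, tree) -> BrownianFit:
    """Directional random walk: BM plus drift in root-to-tip path length.

    Generalized least squares of y on [1, h] with covariance sigma2 * V,
    where h is the vector of root-to-tip path lengths.  Only identifiable
    on non-ultrametric trees (h must vary across tips).
    """
    V = tree if isinstance(tree, PhyloCovariance) else vcv_from_tree(tree)
    y = np.asarray(y, float)
    h = np.diag(V.matrix).copy()
    if np.ptp(h) <= 1e-10 * max(abs(h).max(), 1.0):
        raise IdentifiabilityError(
            "tree is ultrametric (equal root-to-tip paths); drift is "
            "unidentifiable"
        )
    X = np.column_stack([np.ones_like(h), h])
    beta, sigma2, ll = gls_profile(y, V.matrix, X)
    return BrownianFit(alpha=float(beta[0]), sigma2=sigma2, lam=V.lam,
                       loglik=ll, n_params=2, beta=float(beta[1]))


def lr_test(loglik_alt: float, loglik_null: float, df: int) -> tuple[float, float]:
    """Likelihood-ratio statistic 2*(alt - null), clipped at 0, vs chi^2_df."""
    if df < 1:
        raise InvalidParameterError("df must be >= 1")
    stat = max(0.0, 2.0 * (loglik_alt - loglik_null))
    return stat, float(stats.chi2.sf(stat, df))


def lambda_signal_test(y: np.ndarray, tree) -> SignalTestResult:
    """Pagel's-lambda phylogenetic-signal test.

    (i) estimate ML lambda; (ii) refit with lambda fixed at 1 and LR-test
    against the ML fit; (iii) refit with lambda fixed at 0 and LR-test
    against the ML fit.  Both comparisons use df = 1.
    """
    y = np.asarray(y, float)
    if y.shape[0] < 4:
        raise InvalidParameterError("need at least 4 tips for the signal test")
    V = tree if isinstance(tree, PhyloCovariance) else vcv_from_tree(tree)
    fit_ml = fit_brownian(y, V, lam_mode="ml")
    if fit_ml.degenerate:
        return SignalTestResult(lambda_ml=None, loglik_ml=math.nan,
                                loglik_lambda0=math.nan, loglik_lambda1=math.nan,
                                p_vs_0=math.nan, p_vs_1=math.nan, degenerate=True)
    fit0 = fit_brownian(y, V, lam_mode=0.0)
    fit1 = fit_brownian(y, V, lam_mode=1.0)
    _, p0 = lr_test(fit_ml.loglik, fit0.loglik, df=1)
    _, p1 = lr_test(fit_ml.loglik, fit1.loglik, df=1)
    return SignalTestResult(
        lambda_ml=fit_ml.lam,
        loglik_ml=fit_ml.loglik,
        loglik_lambda0=fit0.loglik,
        loglik_lambda1=fit1.loglik,
        p_vs_0=p0,
        p_vs_1=p1,
    )
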