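"""Interspecific allometric regression: OLS, RMA, and PGLS with Pagel's lambda.

Traits and body mass are regressed on a log scale (base 10 by default).
Fits expose log-likelihood (iid or phylogenetic Gaussian errors), AIC with
the residual variance counted as a parameter, R-squared, residuals and
standardized residuals, so species deviating from the allometric trend can
be flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg, optimize

from .errors import (
    DegenerateDataError,
    InvalidComparisonError,
    InvalidInputError,
    InvalidParameterError,
)
from .bm_models import gls_profile, _chol, _LOG2PI
from .treeio import PhyloCovariance, lambda_transform, vcv_from_tree

__all__ = [
    "RegressionFit",
    "ols_fit",
    "rma_fit",
    "pgls_fit",
    "model_select_aic",
    "standardized_residuals",
    "predict_expected",
]


@dataclass(frozen=True)
class RegressionFit:
    """A fitted line (or plane) with diagnostics.

    ``coefficients`` is ``[intercept, slope_1, ...]``.  ``lam`` is the
    Pagel's lambda of a PGLS fit (None for OLS/RMA).  ``log_base`` records
    the log scale the variables were supplied on (used by
    :func:`predict_expected`); None means "not a log-log fit".
    """

    method: str                       # "OLS" | "RMA" | "PGLS"
    coefficients: np.ndarray
    loglik: float
    aic: float
    r_squared: float
    residuals: np.ndarray
    n_params: int                     # k used in AIC (incl. error variance)
    lam: Optional[float] = None
    response: Optional[str] = None
    predictors: tuple = ()
    log_base: Optional[float] = 10.0
    whitened_residuals: Optional[np.ndarray] = None

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def slope(self) -> float:
        return float(self.coefficients[1])


def _as_design(x) -> np.ndarray:
    X = np.asarray(x, float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _gaussian_loglik(resid: np.ndarray) -> float:
    n = resid.shape[0]
    s2 = float(resid @ resid) / n
    if s2 <= 0:
        return math.inf
    return -0.5 * n * (_LOG2PI + math.log(s2) + 1.0)


def ols_fit(y, x, response: Optional[str] = None,
            predictors: Sequence[str] = (), log_base: Optional[float] = 10.0
            ) -> RegressionFit:
    """Ordinary least squares with intercept.

    AIC counts the intercept, each slope and the error variance.
    """
    y = np.asarray(y, float)
    X = _as_design(x)
    n, p = X.shape
    if n <= p + 1:
        raise InvalidInputError(f"need n > number of coefficients ({p + 1})")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise InvalidInputError("design matrix is rank deficient (collinear)")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ll = _gaussian_loglik(resid)
    k = p + 2  # intercept + slopes + error variance
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if tss == 0 else 1.0 - float(resid @ resid) / tss
    return RegressionFit(
        method="OLS", coefficients=beta, loglik=ll, aic=2 * k - 2 * ll,
        r_squared=max(0.0, min(1.0, r2)), residuals=resid, n_params=k,
        response=response, predictors=tuple(predictors), log_base=log_base,
    )


def rma_fit(y, x, response: Optional[str] = None,
            predictors: Sequence[str] = (), log_base: Optional[float] = 10.0
            ) -> RegressionFit:
    """Reduced major axis (bivariate only): slope = sign(r) * sd(y)/sd(x)."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if x.ndim != 1:
        raise InvalidInputError("RMA is bivariate only; pass a 1-D predictor")
    if np.std(x, ddof=1) == 0 or np.std(y, ddof=1) == 0:
        raise InvalidInputError("RMA requires nonzero variance in x and y")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = math.copysign(np.std(y, ddof=1) / np.std(x, ddof=1), r if r != 0 else 1.0)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ll = _gaussian_loglik(resid)
    k = 3
    return RegressionFit(
        method="RMA", coefficients=np.array([intercept, slope]), loglik=ll,
        aic=2 * k - 2 * ll, r_squared=r * r, residuals=resid, n_params=k,
        response=response, predictors=tuple(predictors), log_base=log_base,
    )


def pgls_fit(y, x, tree_or_V, lam_mode="ml", response: Optional[str] = None,
             predictors: Sequence[str] = (), log_base: Optional[float] = 10.0,
             grid_size: int = 21) -> RegressionFit:
    """Phylogenetic generalized least squares with (optionally ML) lambda.

    ``lam_mode`` is ``"ml"`` or a fixed value in [0, 1].  R-squared is
    defined against the intercept-only PGLS fit at the same lambda.  With
    lambda = 0 the fit coincides with OLS.
    """
    y = np.asarray(y, float)
    X = _as_design(x)
    n, p = X.shape
    if n <= p + 1:
        raise InvalidInputError(f"need n > number of coefficients ({p + 1})")
    V = tree_or_V if isinstance(tree_or_V, PhyloCovariance) else vcv_from_tree(tree_or_V)
    if V.n != n:
        raise InvalidInputError("response length does not match tree tips")
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise InvalidInputError("design matrix is rank deficient (collinear)")

    def ll_at(lam: float) -> float:
        return gls_profile(y, lambda_transform(V, lam).matrix, design)[2]

    lam_estimated = False
    if lam_mode == "ml":
        lam_estimated = True
        grid = np.linspace(0.0, 1.0, grid_size)
        lls = [ll_at(l) for l in grid]
        k = int(np.argmax(lls))
        res = optimize.minimize_scalar(
            lambda l: -ll_at(l),
            bounds=(grid[max(k - 1, 0)], grid[min(k + 1, grid_size - 1)]),
            method="bounded", options={"xatol": 1e-7},
        )
        cand = [(float(res.x), -float(res.fun))] + list(zip(grid, lls))
        lam, _ = max(cand, key=lambda t: t[1])
    else:
        lam = float(lam_mode)
        if not (0.0 <= lam <= 1.0):
            raise InvalidParameterError("fixed lambda must be in [0, 1]")

    Vl = lambda_transform(V, lam).matrix
    beta, sigma2, ll = gls_profile(y, Vl, design)
    resid = y - design @ beta
    L = np.linalg.cholesky(Vl)
    white = np.linalg.solve(L, resid)
    # R^2 against the intercept-only GLS fit at the same lambda
    b0, *_ = gls_profile(y, Vl, np.ones((n, 1)))
    resid0 = y - b0[0]
    white0 = np.linalg.solve(L, resid0)
    rss, rss0 = float(white @ white), float(white0 @ white0)
    r2 = 1.0 if rss0 == 0 else 1.0 - rss / rss0
    k = p + 2 + (1 if lam_estimated else 0)
    return RegressionFit(
        method="PGLS", coefficients=beta, loglik=ll, aic=2 * k - 2 * ll,
        r_squared=max(0.0, min(1.0, r2)), residuals=resid, n_params=k,
        lam=lam, response=response, predictors=tuple(predictors),
        log_base=log_base, whitened_residuals=white,
    )


def model_select_aic(fits: Sequence[RegressionFit]) -> list[RegressionFit]:
    """Rank fits of the same response by ascending AIC (best first)."""
    if not fits:
        raise InvalidComparisonError("no fits to rank")
    responses = {f.response for f in fits}
    if len(responses) > 1:
        raise InvalidComparisonError(
            f"fits compare different responses: {sorted(map(str, responses))}"
        )
    return sorted(fits, key=lambda f: (f.aic, f.n_params))


def standardized_residuals(fit: RegressionFit, flag_at: float = 2.0
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Residuals divided by their sample sd, plus an |z| >= flag_at mask.

    For PGLS the V-whitened residuals are standardized instead, so the
    flagging is on the phylogeny-corrected scale.
    """
    resid = (fit.whitened_residuals if fit.method == "PGLS"
             and fit.whitened_residuals is not None else fit.residuals)
    sd = float(np.std(resid, ddof=1))
    # numerically perfect fits leave float dust; don't standardize it
    if sd <= 1e-8 * max(1.0, float(np.max(np.abs(resid), initial=0.0))) or sd == 0:
        z = np.zeros_like(resid)
    else:
        z = resid / sd
    return z, np.abs(z) >= flag_at


def predict_expected(fit: RegressionFit, body_mass: float) -> float:
    """Expected trait value (original units) at a given body mass (kg).

    The fit must be on log-transformed variables; the fitted line is
    evaluated at log(body_mass) and back-transformed.
    """
    if body_mass <= 0:
        raise InvalidInputError("body mass must be positive")
    if fit.log_base is None:
        raise InvalidInputError("fit is not on a log scale; cannot back-transform")
    if len(fit.coefficients) != 2:
        raise InvalidInputError("predict_expected requires a bivariate fit")
    lx = math.log(body_mass, fit.log_base)
    ly = fit.intercept + fit.slope * lx
    return float(fit.log_base ** ly)
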