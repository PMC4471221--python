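"""Permutation two-sample tests, coefficients of variation, and PCA.

The permutation test is exact (full enumeration of label arrangements) when
the number of arrangements does not exceed the requested permutation count,
and Monte Carlo otherwise, with the add-one p-value estimator so p can
never be zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy.special import comb

from .errors import DegenerateDataError, InvalidInputError

__all__ = [
    "PermutationResult",
    "PcaResult",
    "permutation_ttest",
    "coefficient_of_variation",
    "pca",
]


@dataclass(frozen=True)
class PermutationResult:
    t_observed: float
    p: float
    n_permutations: int
    seed: Optional[int]
    exhaustive: bool = False


@dataclass(frozen=True)
class PcaResult:
    percent_variance: np.ndarray     # per component, sums to 100
    scores: np.ndarray               # specimens x components
    loadings: np.ndarray             # variables x components, orthonormal
    factor_map: np.ndarray           # corr(variable, component scores)
    variable_names: tuple = ()
    scale_mode: str = "correlation"


def _pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.shape[0], b.shape[0]
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if sp2 == 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb)))


def permutation_ttest(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> PermutationResult:
    """Two-sided Monte Carlo permutation test on the pooled-variance t.

    Switches to exhaustive enumeration of all C(na+nb, na) label
    arrangements whenever that count does not exceed ``n_perm`` (the p is
    then exact); otherwise ``p = (1 + #{|t*| >= |t|}) / (n_perm + 1)``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise InvalidInputError("each sample needs at least 2 observations")
    t_obs = _pooled_t(a, b)
    pooled = np.concatenate([a, b])
    na = a.shape[0]
    total = int(comb(pooled.shape[0], na, exact=True))
    if total <= n_perm:
        count = 0
        idx_all = range(pooled.shape[0])
        for pick in combinations(idx_all, na):
            mask = np.zeros(pooled.shape[0], bool)
            mask[list(pick)] = True
            t = _pooled_t(pooled[mask], pooled[~mask])
            if abs(t) >= abs(t_obs) - 1e-12:
                count += 1
        return PermutationResult(t_obs, count / total, total, seed, exhaustive=True)
    rng = np.random.default_rng(seed)
    # canonicalize so the Monte-Carlo stream (and hence p) is exactly
    # invariant under swapping the two group labels
    pooled = np.sort(pooled)
    n_small = min(na, b.shape[0])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        t = _pooled_t(perm[:n_small], perm[n_small:])
        if abs(t) >= abs(t_obs) - 1e-12:
            count += 1
    return PermutationResult(t_obs, (1 + count) / (n_perm + 1), n_perm, seed)


def coefficient_of_variation(sample: Sequence[float]) -> float:
    """Sample sd (n-1 denominator) over the sample mean."""
    x = np.asarray(sample, float)
    if x.shape[0] < 2:
        raise InvalidInputError("CV needs at least 2 observations")
    m = x.mean()
    if m == 0.0:
        raise DegenerateDataError("zero mean; CV undefined")
    return float(x.std(ddof=1) / m)


def pca(
    traits: np.ndarray,
    scale_mode: str = "correlation",
    variable_names: Sequence[str] = (),
) -> PcaResult:
    """PCA by eigen-decomposition of the correlation or covariance matrix.

    The sign convention fixes each component so its largest-magnitude
    loading is positive.  The factor map holds the Pearson correlation of
    each variable with each component's scores.
    """
    X = np.asarray(traits, float)
    if X.ndim != 2:
        raise InvalidInputError("traits must be a 2-D specimen x variable matrix")
    n, p = X.shape
    if n <= p:
        raise InvalidInputError("need more specimens than variables")
    if np.isnan(X).any():
        raise InvalidInputError(
            "missing values present; supply a complete-case matrix"
        )
    if scale_mode not in ("correlation", "covariance"):
        raise InvalidInputError("scale_mode must be 'correlation' or 'covariance'")
    centered = X - X.mean(axis=0)
    if scale_mode == "correlation":
        sd = centered.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise DegenerateDataError("a variable has zero variance")
        centered = centered / sd
    cov = (centered.T @ centered) / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # largest-|loading|-positive sign convention
    for j in range(p):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    scores = centered @ eigvec
    percent = 100.0 * eigval / eigval.sum()
    fmap = np.zeros((p, p))
    for v in range(p):
        for cpt in range(p):
            sc = scores[:, cpt]
            if sc.std() == 0 or centered[:, v].std() == 0:
                fmap[v, cpt] = 0.0
            else:
                fmap[v, cpt] = np.corrcoef(centered[:, v], sc)[0, 1]
    return PcaResult(
        percent_variance=percent, scores=scores, loadings=eigvec,
        factor_map=fmap, variable_names=tuple(variable_names),
        scale_mode=scale_mode,
    )
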