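"""Bayesian ancestral states under lambda-scaled Brownian motion.

The sampler is Metropolis-within-Gibbs: the root mean alpha and the
internal-node states have exact Gaussian conditionals and are sampled
directly; sigma2 (log scale) and lambda move by random-walk Metropolis.
Priors are an improper flat prior on alpha, Jeffreys 1/sigma2 on sigma2 and
uniform(0, 1) on lambda; all configurable.

An analytic conditional (:func:`analytic_ancestral`) provides the exact
Gaussian posterior of any node state for *fixed* parameters and doubles as
the oracle for the MCMC.  Fossil values are compared to node posteriors by
Z-scores with one-tailed normal p-values; fossils never enter the
reconstruction itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
from scipy import linalg, stats

from .errors import DegenerateDataError, InvalidInputError, InvalidParameterError
from .treeio import PhyloCovariance, lambda_transform, node_depths, vcv_from_tree

__all__ = [
    "ChainConfig",
    "AncestralPosterior",
    "FossilDeviation",
    "internal_node_ids",
    "analytic_ancestral",
    "mcmc_ancestral",
    "zscore_fossil",
]


@dataclass(frozen=True)
class ChainConfig:
    """MCMC chain settings.  Defaults give 5,000 retained samples."""

    iterations: int = 110_000
    burn_in: int = 10_000
    thinning: int = 20
    seed: int = 0
    sigma2_step: float = 0.6     # sd of the log-sigma2 random walk
    lambda_step: float = 0.12    # sd of the lambda random walk (reflected)
    fixed_alpha: Optional[float] = None
    fixed_sigma2: Optional[float] = None
    fixed_lambda: Optional[float] = None
    ess_threshold: float = 200.0

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


@dataclass
class AncestralPosterior:
    """Posterior samples and summary for one internal node."""

    node_id: str
    samples: np.ndarray
    config: ChainConfig
    warnings: tuple = ()

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def sd(self) -> float:
        return float(self.samples.std(ddof=1))

    def quantile(self, q) -> float:
        return float(np.quantile(self.samples, q))


@dataclass(frozen=True)
class FossilDeviation:
    """Z-score placement of a fossil value against a node posterior."""

    fossil: str
    trait: str
    node_id: str
    z: float
    p: float
    tail: str
    significant: bool


def _node_id(node: dendropy.Node) -> str:
    tips = sorted(lf.taxon.label for lf in node.leaf_iter())
    return "|".join(tips)


def internal_node_ids(tree: dendropy.Tree) -> list[str]:
    """Stable ids ("tipA|tipB|...") for all internal nodes, preorder."""
    return [_node_id(nd) for nd in tree.preorder_internal_node_iter()]


def _node_tip_geometry(tree: dendropy.Tree, V: PhyloCovariance):
    """Per internal node: depth and vector of shared depths with every tip.

    Shared depth of node m with tip i is the root-to-MRCA(m, i) path
    length: depth(m) if i descends from m, else the depth of their MRCA.
    """
    depths = node_depths(tree)
    order = {label: i for i, label in enumerate(V.tip_order)}
    n = len(order)
    out = []
    for node in tree.preorder_internal_node_iter():
        d_m = depths[node]
        shared = np.zeros(n)
        # ancestors of m with their depths, for tips outside m's clade
        anc_depth = {}
        p = node
        while p is not None:
            anc_depth[p] = depths[p]
            p = p.parent_node
        desc = {lf.taxon.label for lf in node.leaf_iter()}
        for leaf in tree.leaf_node_iter():
            i = order[leaf.taxon.label]
            if leaf.taxon.label in desc:
                shared[i] = d_m
            else:
                q = leaf.parent_node
                while q not in anc_depth:
                    q = q.parent_node
                shared[i] = anc_depth[q]
        out.append((_node_id(node), d_m, shared))
    return out


def analytic_ancestral(
    y: np.ndarray,
    tree: dendropy.Tree,
    sigma2: float,
    lam: float,
    node_id: Optional[str] = None,
    alpha: Optional[float] = None,
    tip_order: Optional[Sequence[str]] = None,
) -> dict[str, tuple[float, float]]:
    """Exact Gaussian conditional of internal-node states given tip data.

    With ``alpha`` given, returns the conditional for fixed parameters.
    With ``alpha=None`` the root mean is integrated out under a flat prior,
    so the root posterior mean is the phylogenetically weighted mean
    (1' V^-1 y) / (1' V^-1 1).

    Returns ``{node_id: (mean, sd)}``; restrict to one node with
    ``node_id``.
    """
    if sigma2 <= 0:
        raise InvalidParameterError("sigma2 must be > 0")
    V = vcv_from_tree(tree)
    if tip_order is not None and tuple(tip_order) != V.tip_order:
        idx = [list(tip_order).index(t) for t in V.tip_order]
        y = np.asarray(y, float)[idx]
    else:
        y = np.asarray(y, float)
    Vl = lambda_transform(V, lam).matrix
    c = linalg.cho_factor(Vl, lower=True)
    ones = np.ones(V.n)
    Vi_1 = linalg.cho_solve(c, ones)
    denom = float(ones @ Vi_1)
    alpha_hat = float(Vi_1 @ y) / denom if alpha is None else alpha
    r = y - alpha_hat
    Vi_r = linalg.cho_solve(c, r)

    results = {}
    for nid, d_m, shared in _node_tip_geometry(tree, V):
        if node_id is not None and nid != node_id:
            continue
        cmt = lam * shared            # cov(node, tips) / sigma2
        var_m = lam * d_m             # var(node) / sigma2
        Vi_c = linalg.cho_solve(c, cmt)
        mean = alpha_hat + float(cmt @ Vi_r)
        var = var_m - float(cmt @ Vi_c)
        if alpha is None:
            # flat-prior alpha uncertainty propagates through the conditional
            sens = 1.0 - float(cmt @ Vi_1)
            var += sens * sens / denom
        var = max(var, 0.0) * sigma2
        results[nid] = (mean, math.sqrt(var))
    if node_id is not None and node_id not in results:
        raise InvalidInputError(f"unknown internal node id {node_id!r}")
    return results


def _ess(x: np.ndarray) -> float:
    """Effective sample size via initial positive autocorrelation sums."""
    n = x.shape[0]
    if n < 10 or np.std(x) <= 1e-12 * max(1.0, float(abs(x.mean()))):
        return float(n)  # (numerically) constant chain: exact draws
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for k in range(1, min(n, 1000)):
        if acf[k] <= 0.0:
            break
        s += acf[k]
    return n / (1.0 + 2.0 * s)


def mcmc_ancestral(
    y: np.ndarray,
    tree: dendropy.Tree,
    config: ChainConfig,
    tip_order: Optional[Sequence[str]] = None,
) -> dict[str, AncestralPosterior]:
    """Posterior samples of internal-node states under lambda-scaled BM.

    Samples (alpha, sigma2, lambda) and, at each retained iteration, draws
    every internal-node state from its exact Gaussian conditional given the
    current parameters.  Fully reproducible for a fixed seed.  Returns a
    posterior per internal node, plus the parameter chains under the ids
    ``"_alpha"``, ``"_sigma2"``, ``"_lambda"``.
    """
    V = vcv_from_tree(tree)
    y = np.asarray(y, float)
    if tip_order is not None and tuple(tip_order) != V.tip_order:
        idx = [list(tip_order).index(t) for t in V.tip_order]
        y = y[idx]
    n = V.n
    if n < 2:
        raise InvalidInputError("need at least 2 tips for the MCMC")
    if np.ptp(y) == 0:
        raise DegenerateDataError("trait is constant across tips")
    rng = np.random.default_rng(config.seed)
    geometry = _node_tip_geometry(tree, V)
    node_ids = [g[0] for g in geometry]
    ones = np.ones(n)

    cache: dict[float, dict] = {}

    def setup(lam: float) -> dict:
        if lam in cache:
            return cache[lam]
        Vl = lambda_transform(V, lam).matrix
        c = linalg.cho_factor(Vl, lower=True)
        Vi_1 = linalg.cho_solve(c, ones)
        Vi_y = linalg.cho_solve(c, y)
        logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
        denom = float(ones @ Vi_1)
        node_w = []
        node_v = []
        for nid, d_m, shared in geometry:
            cmt = lam * shared
            w = linalg.cho_solve(c, cmt)
            node_w.append(w)
            node_v.append(max(lam * d_m - float(cmt @ w), 0.0))
        entry = {
            "Vi_1": Vi_1, "Vi_y": Vi_y, "logdet": logdet, "denom": denom,
            "W": np.array(node_w), "v": np.array(node_v),
        }
        if len(cache) > 64:
            cache.clear()
        cache[lam] = entry
        return entry

    def loglik(alpha, sigma2, entry):
        quad = float((y - alpha) @ (entry["Vi_y"] - alpha * entry["Vi_1"]))
        return -0.5 * (n * math.log(2 * math.pi * sigma2)
                       + entry["logdet"] + quad / sigma2)

    # initial state
    lam = config.fixed_lambda if config.fixed_lambda is not None else 0.5
    entry = setup(lam)
    alpha = (config.fixed_alpha if config.fixed_alpha is not None
             else float(entry["Vi_1"] @ y) / entry["denom"])
    if config.fixed_sigma2 is not None:
        sigma2 = config.fixed_sigma2
    else:
        r = y - alpha
        quad = float(r @ (entry["Vi_y"] - alpha * entry["Vi_1"]))
        sigma2 = max(quad / n, 1e-12)

    n_nodes = len(node_ids)
    kept = np.empty((config.n_retained, n_nodes))
    kept_params = np.empty((config.n_retained, 3))
    k = 0
    ll = loglik(alpha, sigma2, entry)
    for it in range(config.iterations):
        # alpha | rest : exact Gaussian (flat prior)
        if config.fixed_alpha is None:
            mean_a = float(entry["Vi_1"] @ y) / entry["denom"]
            sd_a = math.sqrt(sigma2 / entry["denom"])
            alpha = mean_a + sd_a * rng.standard_normal()
            ll = loglik(alpha, sigma2, entry)
        # sigma2 | rest : random walk on log sigma2, Jeffreys prior
        if config.fixed_sigma2 is None:
            prop = sigma2 * math.exp(config.sigma2_step * rng.standard_normal())
            ll_prop = loglik(alpha, prop, entry)
            # Jeffreys 1/sigma2 prior and log-scale Jacobian cancel
            if math.log(rng.random()) < ll_prop - ll:
                sigma2, ll = prop, ll_prop
        # lambda | rest : reflected random walk, uniform(0,1) prior
        if config.fixed_lambda is None:
            prop = lam + config.lambda_step * rng.standard_normal()
            prop = abs(prop)
            if prop > 1.0:
                prop = 2.0 - prop
            prop = min(max(prop, 0.0), 1.0)
            e_prop = setup(round(prop, 10))
            ll_prop = loglik(alpha, sigma2, e_prop)
            if math.log(rng.random()) < ll_prop - ll:
                lam, entry, ll = round(prop, 10), e_prop, ll_prop
        # node states | parameters : exact Gaussian conditionals
        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
            means = alpha + entry["W"] @ (y - alpha)
            sds = np.sqrt(sigma2 * entry["v"])
            kept[k] = means + sds * rng.standard_normal(n_nodes)
            kept_params[k] = (alpha, sigma2, lam)
            k += 1

    posteriors = {}
    warn: list[str] = []
    for j, nid in enumerate(node_ids):
        ess = _ess(kept[:k, j])
        w = ()
        if ess < config.ess_threshold:
            msg = f"low effective sample size ({ess:.0f}) at node {nid}"
            warn.append(msg)
            w = (msg,)
        posteriors[nid] = AncestralPosterior(nid, kept[:k, j].copy(), config, w)
    for j, pid in enumerate(("_alpha", "_sigma2", "_lambda")):
        posteriors[pid] = AncestralPosterior(pid, kept_params[:k, j].copy(), config)
    if warn:
        import warnings as _warnings
        _warnings.warn("; ".join(warn), RuntimeWarning, stacklevel=2)
    return posteriors


def zscore_fossil(
    fossil_value: float,
    posterior: AncestralPosterior,
    tail: str = "auto",
    fossil: str = "",
    trait: str = "",
    alpha_level: float = 0.05,
) -> FossilDeviation:
    """Place a fossil value against a node posterior by Z-score.

    ``tail`` is ``"left"``, ``"right"`` or ``"auto"`` (the side the fossil
    lies on).  p is the one-tailed standard-normal probability.
    """
    sd = posterior.sd
    if not sd > 0:
        raise DegenerateDataError("posterior sd is zero; Z-score undefined")
    z = (fossil_value - posterior.mean) / sd
    if tail == "auto":
        tail = "left" if z < 0 else "right"
    if tail == "left":
        p = float(stats.norm.cdf(z))
    elif tail == "right":
        p = float(stats.norm.sf(z))
    else:
        raise InvalidParameterError("tail must be 'left', 'right' or 'auto'")
    return FossilDeviation(
        fossil=fossil, trait=trait, node_id=posterior.node_id,
        z=float(z), p=p, tail=tail, significant=p <= alpha_level,
    )
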