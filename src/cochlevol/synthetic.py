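"""Synthetic inputs with recorded ground truth for recovery testing.

Every generator returns (or embeds) a :class:`SyntheticTruth` carrying the
parameters needed to recompute the dataset exactly, so a round-trip
"generate -> measure/fit -> compare to truth" harness can exercise every
pipeline stage offline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import dendropy
import numpy as np
import pandas as pd
from scipy import integrate

from .errors import InvalidInputError, InvalidParameterError
from .morphometry import LandmarkPath
from .treeio import read_newick, vcv_from_tree

__all__ = [
    "SyntheticTruth",
    "simulate_tree",
    "simulate_bm_tips",
    "simulate_allometric_table",
    "generate_spiral_landmarks",
    "generate_window_outline",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters of a generated dataset."""

    generator: str
    params: dict
    seed: Optional[int]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=float)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation matrix (QR of a Gaussian matrix)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] = -q[:, 2]
    return q


def simulate_tree(
    n_tips: int,
    kind: str = "pure-birth",
    seed: Optional[int] = None,
    birth_rate: float = 1.0,
    jitter_sd: float = 0.0,
) -> dendropy.Tree:
    """Simulate a rooted tree with positive branch lengths.

    ``kind`` is ``"pure-birth"`` (Yule), ``"caterpillar"`` (fully pectinate,
    unit branches) or ``"star"``.  ``jitter_sd > 0`` multiplies every branch
    by an independent lognormal factor, producing a non-ultrametric
    phylogram (needed for directional-model tests).
    """
    if n_tips < 2:
        raise InvalidInputError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    labels = [f"t{i + 1}" for i in range(n_tips)]
    if kind == "star":
        newick = "(" + ",".join(f"{l}:1.0" for l in labels) + ");"
    elif kind == "caterpillar":
        s = f"({labels[0]}:1.0,{labels[1]}:1.0)"
        for l in labels[2:]:
            s = f"({s}:1.0,{l}:1.0)"
        newick = s + ";"
    elif kind == "pure-birth":
        newick = _yule_newick(n_tips, labels, birth_rate, rng)
    else:
        raise InvalidParameterError(f"unknown tree kind {kind!r}")
    tree = read_newick(newick)
    if jitter_sd > 0:
        for edge in tree.preorder_edge_iter():
            if edge.tail_node is None or edge.length is None:
                continue
            edge.length = float(edge.length * rng.lognormal(0.0, jitter_sd))
    return tree


class _YuleNode:
    __slots__ = ("label", "birth", "children", "length")

    def __init__(self, label, birth):
        self.label = label
        self.birth = birth
        self.children = None
        self.length = None

    def newick(self):
        if self.children is None:
            return f"{self.label}:{self.length:.10f}"
        inner = ",".join(ch.newick() for ch in self.children)
        return f"({inner}):{self.length:.10f}"


def _yule_newick(n_tips, labels, birth_rate, rng):
    """Pure-birth (Yule) tree as a Newick string with positive lengths."""
    root = _YuleNode(None, 0.0)
    root.children = [_YuleNode(0, 0.0), _YuleNode(1, 0.0)]
    root.length = 0.0
    active = list(root.children)
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        node.length = t - node.birth
        node.children = [_YuleNode(None, t), _YuleNode(None, t)]
        active.extend(node.children)
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for k, node in enumerate(active):
        node.length = t - node.birth
    # assign labels left-to-right over the final tips
    counter = iter(labels)
    def assign(node):
        if node.children is None:
            node.label = next(counter)
        else:
            for ch in node.children:
                assign(ch)
    assign(root)
    inner = ",".join(ch.newick() for ch in root.children)
    return f"({inner});"


def _lambda_stretch(tree: dendropy.Tree, lam: float) -> dendropy.Tree:
    """Rescale internal branches by lambda, keeping tip depths unchanged."""
    from .treeio import node_depths

    out = tree.clone(depth=1)
    depths = node_depths(tree)
    orig = {}
    for nd_o, nd_c in zip(tree.preorder_node_iter(), out.preorder_node_iter()):
        orig[nd_c] = nd_o
    for node in out.preorder_node_iter():
        o = orig[node]
        if o.edge.length is None:
            continue
        if node.is_leaf():
            parent_depth = depths[o.parent_node] if o.parent_node else 0.0
            node.edge.length = depths[o] - lam * parent_depth
        else:
            node.edge.length = lam * o.edge.length
    return out


def simulate_bm_tips(
    tree: dendropy.Tree,
    alpha: float,
    sigma2: float,
    lam: float = 1.0,
    seed: Optional[int] = None,
    keep_internal: bool = False,
):
    """Simulate Brownian tip values by recursion down the lambda-stretched tree.

    Returns ``(values, truth)`` where *values* maps tip label to trait value
    (and internal node states when ``keep_internal``); the draw is exactly
    MVN(alpha * 1, sigma2 * V_lambda).
    """
    if sigma2 < 0:
        raise InvalidParameterError("sigma2 must be >= 0")
    if not (0.0 <= lam <= 1.0):
        raise InvalidParameterError("lambda must be in [0, 1]")
    rng = np.random.default_rng(seed)
    work = _lambda_stretch(tree, lam) if lam != 1.0 else tree
    states: dict = {}
    tip_values: dict[str, float] = {}
    internal: dict[str, float] = {}
    for node, orig in zip(work.preorder_node_iter(), tree.preorder_node_iter()):
        parent = node.parent_node
        base = alpha if parent is None else states[parent]
        b = node.edge.length or 0.0
        val = base + math.sqrt(sigma2 * b) * rng.standard_normal() if b > 0 else base
        states[node] = float(val)
        if node.is_leaf():
            tip_values[node.taxon.label] = float(val)
        elif keep_internal:
            tips = sorted(lf.taxon.label for lf in orig.leaf_iter())
            internal["|".join(tips)] = float(val)
    truth = SyntheticTruth(
        "simulate_bm_tips",
        {"alpha": alpha, "sigma2": sigma2, "lambda": lam,
         "internal_states": internal if keep_internal else None},
        seed,
    )
    return tip_values, truth


def simulate_allometric_table(
    tree: dendropy.Tree,
    slope: float,
    intercept: float,
    resid_sd: float,
    resid_lam: float = 1.0,
    seed: Optional[int] = None,
    mass_sigma2: float = 0.25,
    mass_mean: float = 1.0,
    trait: str = "RECL",
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Species table with a known log-log allometry and phylogenetic residuals.

    log10 body mass evolves by BM on the tree; log10 trait = intercept +
    slope * log10(mass) + a phylogenetic residual with Pagel's lambda
    ``resid_lam`` and marginal sd ``resid_sd``.  The emitted table is
    back-transformed and carries alternating clade tags.
    """
    rng = np.random.default_rng(seed)
    s1, s2 = rng.integers(0, 2**31 - 1, size=2)
    logmass, _ = simulate_bm_tips(tree, mass_mean, mass_sigma2, 1.0, seed=int(s1))
    labels = list(logmass)
    V = vcv_from_tree(tree)
    mean_depth = float(np.mean(np.diag(V.matrix)))
    if resid_sd > 0:
        resid_sigma2 = resid_sd**2 / mean_depth
        resid, _ = simulate_bm_tips(tree, 0.0, resid_sigma2, resid_lam, seed=int(s2))
    else:
        resid = {l: 0.0 for l in labels}
    rows = []
    for i, label in enumerate(V.tip_order):
        lm = logmass[label]
        lt = intercept + slope * lm + resid[label]
        rows.append({
            "species": label,
            "body_mass_kg": 10.0 ** lm,
            trait: 10.0 ** lt,
            "clade": "hominoid" if i % 2 == 0 else "cercopithecoid",
        })
    table = pd.DataFrame(rows)
    truth = SyntheticTruth(
        "simulate_allometric_table",
        {"slope": slope, "intercept": intercept, "resid_sd": resid_sd,
         "resid_lambda": resid_lam, "mass_sigma2": mass_sigma2,
         "trait": trait},
        seed,
    )
    return table, truth


def generate_spiral_landmarks(
    turns: float,
    r_start: float,
    r_end: float,
    points_per_turn: int = 240,
    axial_rise: float = 0.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> tuple[LandmarkPath, SyntheticTruth]:
    """Archimedean spiral landmark path with analytically known truth.

    r(theta) is linear from ``r_start`` (basal end, first point) to
    ``r_end`` (apical end); an optional conical rise of ``axial_rise`` mm
    per turn and isotropic Gaussian noise are applied before a random rigid
    rotation + translation.  Truth records turns, the two radii, the exact
    CUR (= r_start / r_end) and the arc length by numerical quadrature.
    """
    if turns <= 0:
        raise InvalidParameterError("turns must be > 0")
    if not (r_start > r_end > 0):
        raise InvalidParameterError("need r_start > r_end > 0")
    rng = np.random.default_rng(seed)
    theta_total = 2.0 * math.pi * turns
    n_points = max(int(round(points_per_turn * turns)) + 1, 8)
    theta = np.linspace(0.0, theta_total, n_points)
    k = (r_end - r_start) / theta_total
    r = r_start + k * theta
    rise_rate = axial_rise / (2.0 * math.pi)

    def integrand(t):
        return np.sqrt((r_start + k * t) ** 2 + k**2 + rise_rate**2)

    arc, _ = integrate.quad(integrand, 0.0, theta_total, limit=200)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), rise_rate * theta])
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
    rot = _random_rotation(rng)
    shift = rng.uniform(-10.0, 10.0, size=3)
    pts = pts @ rot.T + shift
    path = LandmarkPath(pts, role="spiral", start="base")
    truth = SyntheticTruth(
        "generate_spiral_landmarks",
        {"turns": turns, "r_start": r_start, "r_end": r_end,
         "cur": r_start / r_end, "arc_length": arc,
         "points_per_turn": points_per_turn, "axial_rise": axial_rise,
         "noise_sd": noise_sd},
        seed,
    )
    return path, truth


def generate_window_outline(
    semi_major: float,
    semi_minor: float,
    n_points: int = 180,
    plane_tilt: float = 0.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> tuple[LandmarkPath, SyntheticTruth]:
    """Elliptical window outline in an oblique plane; truth area = pi*a*b."""
    if not (semi_major >= semi_minor > 0):
        raise InvalidParameterError("need semi_major >= semi_minor > 0")
    rng = np.random.default_rng(seed)
    phi = np.linspace(0.0, 2.0 * math.pi, n_points, endpoint=False)
    pts = np.column_stack([
        semi_major * np.cos(phi), semi_minor * np.sin(phi), np.zeros_like(phi)
    ])
    if plane_tilt != 0.0:
        c, s = math.cos(plane_tilt), math.sin(plane_tilt)
        tilt = np.array([[1, 0, 0], [0, c, -s], [0, s, c]], float)
        pts = pts @ tilt.T
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
    rot = _random_rotation(rng)
    pts = pts @ rot.T + rng.uniform(-5.0, 5.0, size=3)
    path = LandmarkPath(pts, role="window-outline")
    truth = SyntheticTruth(
        "generate_window_outline",
        {"semi_major": semi_major, "semi_minor": semi_minor,
         "area": math.pi * semi_major * semi_minor,
         "plane_tilt": plane_tilt, "noise_sd": noise_sd},
        seed,
    )
    return path, truth
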