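"""Phylogeny input, trait-table alignment and Brownian covariance matrices.

Trees are rooted phylograms in Newick format with branch lengths on every
edge.  The shared-path-length (variance-covariance) matrix V has diagonal
entries equal to root-to-tip path lengths and off-diagonal entries equal to
the root-to-MRCA distance of each tip pair.  Pagel's lambda rescales the
off-diagonal entries only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    InvalidParameterError,
    NewickParseError,
    UnrootedTreeError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PhyloCovariance",
    "read_newick",
    "write_newick",
    "tip_labels",
    "node_depths",
    "tip_depths",
    "vcv_from_tree",
    "lambda_transform",
    "align_table_to_tree",
]


@dataclass(frozen=True)
class PhyloCovariance:
    """Shared-path-length matrix for a set of tips, with the lambda applied."""

    matrix: np.ndarray
    tip_order: tuple
    lam: float = 1.0

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InvalidParameterError("covariance matrix must be square")
        if m.shape[0] != len(self.tip_order):
            raise InvalidParameterError("tip order length must match matrix")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "tip_order", tuple(self.tip_order))

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def read_newick(source: str) -> dendropy.Tree:
    """Parse a rooted Newick phylogram from a string or file path.

    Every edge (except the root edge) must carry a branch length; missing
    lengths are an error, never silently defaulted.  Trees explicitly
    flagged unrooted (``[&U]``) are rejected.
    """
    if "(" in source:
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="default-rooted",
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:  # dendropy raises various DataError subclasses
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    if not tree.is_rooted:
        raise UnrootedTreeError("tree is flagged unrooted ([&U]); not supported")
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue  # root edge; a missing root length is conventional
        if edge.length is None:
            tips = sorted(
                lf.taxon.label for lf in edge.head_node.leaf_iter()
            )
            raise NewickParseError(
                f"missing branch length on the edge above clade {{{','.join(tips)}}}"
            )
        if edge.length < 0:
            raise NewickParseError("negative branch length")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".12g",
    ).strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def node_depths(tree: dendropy.Tree) -> dict:
    """Root-to-node path length for every node (root edge length included)."""
    depths = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        depths[node] = edge + (depths[parent] if parent is not None else 0.0)
    return depths


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    depths = node_depths(tree)
    return {leaf.taxon.label: depths[leaf] for leaf in tree.leaf_node_iter()}


def vcv_from_tree(tree: dendropy.Tree) -> PhyloCovariance:
    """Brownian variance-covariance matrix of a rooted phylogram (lambda = 1).

    ``V[i, i]`` is the root-to-tip path length of tip *i*; ``V[i, j]`` the
    root-to-MRCA path length of the pair.  Polytomies are fine (they just
    produce tied off-diagonals).
    """
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    if len(set(labels)) != len(labels):
        raise NewickParseError("duplicate tip labels")
    index = {lf: i for i, lf in enumerate(leaves)}
    depths = node_depths(tree)
    n = len(leaves)
    V = np.zeros((n, n))
    for lf in leaves:
        V[index[lf], index[lf]] = depths[lf]
    # leaf sets per node, computed postorder
    leafsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[node] = [index[node]]
        else:
            children = [leafsets[c] for c in node.child_nodes()]
            d = depths[node]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            V[i, j] = V[j, i] = d
            leafsets[node] = [i for ch in children for i in ch]
    return PhyloCovariance(matrix=V, tip_order=tuple(labels), lam=1.0)


def lambda_transform(V: PhyloCovariance, lam: float, upper: float = 1.0) -> PhyloCovariance:
    """Scale the off-diagonal entries of V by ``lam``.

    ``lam = 0`` gives a diagonal (star-like) matrix, ``lam = 1`` is the
    identity operation.  Values outside [0, ``upper``] are rejected.
    """
    if not (0.0 <= lam <= upper):
        raise InvalidParameterError(f"lambda must be in [0, {upper}], got {lam}")
    m = V.matrix * lam
    np.fill_diagonal(m, np.diag(V.matrix))
    return PhyloCovariance(matrix=m, tip_order=V.tip_order, lam=lam)


def align_table_to_tree(
    table: pd.DataFrame,
    tree: dendropy.Tree,
    species_column: str = "species",
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Reconcile a species-level trait table with a tree.

    Tips without trait rows are pruned (with a log warning); trait rows
    naming species absent from the tree are an error.  Returns a pruned
    copy of the tree and the table reordered to the pruned tree's tip
    order.  Matching is exact and case-sensitive.
    """
    if species_column not in table.columns:
        raise AlignmentError(f"table lacks a {species_column!r} column")
    species = list(table[species_column].astype(str))
    if len(set(species)) != len(species):
        raise AlignmentError("duplicate species rows in trait table")
    tips = set(tip_labels(tree))
    missing_from_tree = sorted(set(species) - tips)
    if missing_from_tree:
        raise AlignmentError(
            f"trait species absent from tree: {', '.join(missing_from_tree)}"
        )
    keep = set(species)
    if not keep & tips:
        raise AlignmentError("no species shared between table and tree")
    dropped = sorted(tips - keep)
    pruned = tree.clone(depth=1)
    if dropped:
        logger.warning("pruning %d tip(s) without trait rows: %s",
                       len(dropped), ", ".join(dropped))
        pruned.retain_taxa_with_labels(sorted(keep))
    order = tip_labels(pruned)
    ordered = (
        table.set_index(species_column).loc[order].reset_index()
    )
    return pruned, ordered
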