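"""Phylogenetic tree handling and Brownian-motion covariance with Pagel's lambda.

Trees are dendropy ``Tree`` objects read from Newick; all comparative
statistics consume the taxon-by-taxon covariance matrix

    C_lambda[i, j] = lambda * t_ij   (i != j),      C_lambda[i, i] = t_i,

where t_ij is the root-to-MRCA path length shared by tips i and j and
t_i the root-to-tip depth.  lambda = 1 is pure Brownian motion on the
tree; lambda = 0 removes all phylogenetic covariance (a star phylogeny).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import dendropy
import numpy as np

__all__ = [
    "load_tree",
    "tree_from_newick",
    "tree_to_newick",
    "tip_labels",
    "tip_depths",
    "is_ultrametric",
    "bm_covariance",
    "shared_path_matrix",
]


def load_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    _require_branch_lengths(tree)
    return tree


def tree_from_newick(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    _require_branch_lengths(tree)
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def _require_branch_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has edges without branch lengths")


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path lengths, excluding any stem edge above the root.

    History before the root is shared by every tip and carries no
    between-tip contrast, so the covariance construction ignores it
    (the convention of standard comparative methods).
    """
    depths: dict[str, float] = {}

    def walk(node, acc: float) -> None:
        for child in node.child_nodes():
            d = acc + (child.edge.length or 0.0)
            if child.is_leaf():
                depths[child.taxon.label] = d
            else:
                walk(child, d)

    walk(tree.seed_node, 0.0)
    return depths


def is_ultrametric(tree: dendropy.Tree, rtol: float = 1e-6, warn: bool = True) -> bool:
    """Check that all root-to-tip depths agree to relative tolerance ``rtol``."""
    depths = np.array(list(tip_depths(tree).values()))
    ok = bool(np.ptp(depths) <= rtol * max(depths.max(), np.finfo(float).tiny))
    if not ok and warn:
        warnings.warn(
            f"tree is not ultrametric (tip depths span {depths.min():.6g}..{depths.max():.6g})",
            stacklevel=2,
        )
    return ok


def shared_path_matrix(tree: dendropy.Tree, taxa: list[str] | None = None) -> tuple[list[str], np.ndarray]:
    """Root-to-MRCA shared path lengths for every tip pair (lambda = 1 covariance).

    Computed from tip depths and patristic distances:
    t_ij = (t_i + t_j - d_ij) / 2.
    """
    labels = tip_labels(tree)
    if taxa is not None:
        missing = set(taxa) - set(labels)
        if missing:
            raise ValueError(f"taxa absent from tree: {sorted(missing)}")
        labels = list(taxa)
    depth = tip_depths(tree)
    pdm = tree.phylogenetic_distance_matrix()
    tax_of = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        C[i, i] = depth[a]
        for j in range(i + 1, n):
            b = labels[j]
            d = pdm.patristic_distance(tax_of[a], tax_of[b])
            C[i, j] = C[j, i] = 0.5 * (depth[a] + depth[b] - d)
    return labels, C


def bm_covariance(
    tree: dendropy.Tree, lam: float, taxa: list[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance with Pagel's lambda scaling the off-diagonal.

    Parameters
    ----------
    tree
        Rooted tree with branch lengths.
    lam
        Pagel's lambda in [0, 1].
    taxa
        Optional tip order for the returned matrix (default: tree order).
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam!r}")
    labels, C = shared_path_matrix(tree, taxa)
    return labels, apply_lambda(C, lam)


def apply_lambda(C: np.ndarray, lam: float) -> np.ndarray:
    """Multiply off-diagonal entries of a shared-path matrix by lambda."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam!r}")
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out
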