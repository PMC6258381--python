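"""Classical branching statistics of dendritic trees.

These are the morphometric quantities against which the regularity index is
compared: total cable length, branch-point counts, branch order, branch
angle, tree asymmetry, path length, and the hull-normalized densities (cable
per supporting measure, branch points per supporting measure).

All statistics are invariant under rigid motions; total length scales
linearly and hull measures as s^d under uniform scaling s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hulls import Hull
from .trees import NeuronTree, topological_order

__all__ = [
    "TreeStats",
    "total_cable_length",
    "branch_orders",
    "branch_angles",
    "tree_asymmetry",
    "path_lengths",
    "summarize_tree",
]


def _edge_lengths(tree: NeuronTree) -> np.ndarray:
    """Length of the edge above each node (0 for the root)."""
    lengths = np.zeros(tree.n_nodes)
    has_parent = tree.parent >= 0
    lengths[has_parent] = np.linalg.norm(
        tree.coords[has_parent] - tree.coords[tree.parent[has_parent]], axis=1
    )
    return lengths


def total_cable_length(tree: NeuronTree) -> float:
    """Sum of Euclidean lengths of all parent-child edges (micrometers)."""
    return float(_edge_lengths(tree).sum())


def _branch_point_mask(tree: NeuronTree) -> np.ndarray:
    counts = tree.child_counts()
    mask = counts == 2
    mask[tree.root] = False  # the root is a distinguished node, never a BP
    return mask


def branch_orders(tree: NeuronTree) -> tuple[np.ndarray, float]:
    """Branch order per node (number of BPs strictly on the root path) and
    its mean over all nodes."""
    is_bp = _branch_point_mask(tree)
    orders = np.zeros(tree.n_nodes, dtype=int)
    for i in topological_order(tree):
        p = tree.parent[i]
        if p >= 0:
            orders[i] = orders[p] + int(is_bp[p])
    return orders, float(orders.mean())


def branch_angles(tree: NeuronTree) -> tuple[np.ndarray, float]:
    """Angle (radians) between the two daughter segments at each BP, and the
    mean over BPs (NaN when the tree has none).

    The angle uses the immediate daughter segment direction (BP to first
    child node), not the full daughter-branch chord.
    """
    children = tree.children()
    bps = np.flatnonzero(_branch_point_mask(tree))
    angles = np.empty(bps.size)
    for k, b in enumerate(bps):
        c1, c2 = children[b]
        u = tree.coords[c1] - tree.coords[b]
        v = tree.coords[c2] - tree.coords[b]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            angles[k] = 0.0  # zero-length daughter segment (stacked cascade node)
            continue
        cosang = np.clip(u @ v / (nu * nv), -1.0, 1.0)
        angles[k] = np.arccos(cosang)
    mean = float(angles.mean()) if angles.size else float("nan")
    return angles, mean


def _subtree_tp_counts(tree: NeuronTree) -> np.ndarray:
    """Number of termination points in the subtree rooted at each node."""
    counts = tree.child_counts()
    tp = np.where(counts == 0, 1, 0).astype(int)
    for i in topological_order(tree)[::-1]:
        p = tree.parent[i]
        if p >= 0:
            tp[p] += tp[i]
    return tp


def tree_asymmetry(tree: NeuronTree) -> tuple[np.ndarray, float]:
    """Per-BP asymmetry v1/(v1+v2), v1 the smaller daughter termination
    count, and the mean over BPs (NaN when the tree has none).

    0.5 is perfectly balanced; values approach 0 for caterpillar-like trees.
    """
    children = tree.children()
    tp = _subtree_tp_counts(tree)
    bps = np.flatnonzero(_branch_point_mask(tree))
    ratios = np.empty(bps.size)
    for k, b in enumerate(bps):
        c1, c2 = children[b]
        v1, v2 = sorted((tp[c1], tp[c2]))
        ratios[k] = v1 / (v1 + v2)
    mean = float(ratios.mean()) if ratios.size else float("nan")
    return ratios, mean


def path_lengths(tree: NeuronTree) -> tuple[np.ndarray, float]:
    """Path length along the tree from each node to the root, and its mean
    over non-root nodes (0 for a single-node tree)."""
    edge = _edge_lengths(tree)
    plen = np.zeros(tree.n_nodes)
    for i in topological_order(tree):
        p = tree.parent[i]
        if p >= 0:
            plen[i] = plen[p] + edge[i]
    if tree.n_nodes <= 1:
        return plen, 0.0
    mean = float(plen[np.arange(tree.n_nodes) != tree.root].mean())
    return plen, mean


@dataclass
class TreeStats:
    """Bundle of branching statistics for one tree.

    ``cable_density`` is total length per tight-hull measure (µm per µm² or
    µm³); ``bp_density`` is branch points per hull measure.
    """

    total_length: float
    n_branch_points: int
    mean_branch_order: float
    mean_branch_angle: float
    mean_asymmetry: float
    mean_path_length: float
    cable_density: float
    bp_density: float

    COLUMNS = (
        "total_length",
        "n_branch_points",
        "mean_branch_order",
        "mean_branch_angle",
        "mean_asymmetry",
        "mean_path_length",
        "cable_density",
        "bp_density",
    )

    def to_row(self, key: str | None = None) -> pd.DataFrame:
        row = {c: getattr(self, c) for c in self.COLUMNS}
        if key is not None:
            row = {"source": key, **row}
        return pd.DataFrame([row])


def summarize_tree(tree: NeuronTree, hull: Hull) -> TreeStats:
    """All branching statistics of a tree, normalized by a supporting hull.

    The hull should be computed from the tree's own node positions (branch
    points, typically); a zero-measure hull is an error.
    """
    if hull.measure <= 0:
        raise ValueError("hull measure must be positive to form densities")
    n_bp = int(_branch_point_mask(tree).sum())
    return TreeStats(
        total_length=total_cable_length(tree),
        n_branch_points=n_bp,
        mean_branch_order=branch_orders(tree)[1],
        mean_branch_angle=branch_angles(tree)[1],
        mean_asymmetry=tree_asymmetry(tree)[1],
        mean_path_length=path_lengths(tree)[1],
        cable_density=total_cable_length(tree) / hull.measure,
        bp_density=n_bp / hull.measure,
    )
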