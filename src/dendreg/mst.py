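"""Extended minimum-spanning-tree dendrite models.

Synthetic dendrites are grown over a set of target points (a proxy for
synaptic input locations) by greedily attaching, at every step, the
unconnected target t and tree node v that minimize

    ||t - v|| + bf * (pathlength(root -> v) + ||t - v||)

i.e. the incremental cable cost plus ``bf`` times the incremental root-path
cost.  At bf = 0 this is Prim's algorithm and the result matches the plain
Euclidean minimum spanning tree (subject to the degree cap); larger bf trades
cable for shorter, more direct paths to the root.  Multifurcations are not
allowed: every node, including the root, accepts at most two children, so
grown trees are binary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist, pdist, squareform

from .trees import NeuronTree, PointCloud

__all__ = ["MSTConfig", "grow_mst", "euclidean_mst_oracle"]


@dataclass
class MSTConfig:
    """Growth parameters: balancing factor ``bf`` (dimensionless, >= 0;
    realistic dendrites sit between 0.2 and 0.8) and the root position
    (defaults to the center of the targets' bounding box — the region
    center for clouds filling their region)."""

    bf: float = 0.5
    root: np.ndarray | None = None
    max_children: int = 2  # fixed: no multifurcations

    def __post_init__(self) -> None:
        if self.bf < 0:
            raise ValueError("bf must be >= 0")
        if self.max_children != 2:
            raise ValueError("trees are binary: max_children is fixed at 2")
        if self.root is not None:
            self.root = np.asarray(self.root, dtype=float)


def grow_mst(targets: PointCloud, config: MSTConfig | None = None, **kwargs) -> NeuronTree:
    """Grow a binary extended-MST tree over all target points.

    Ties in the greedy attachment cost are broken deterministically by
    lowest target index, then lowest tree-node index.  Targets coincident
    with the root or each other attach with zero-length edges.  Returns an
    SWC-compatible tree: node 1 is the root (region 1), targets become
    dendrite nodes (region 3) in attachment order.
    """
    if config is None:
        config = MSTConfig(**kwargs)
    pts = targets.points
    n, d = pts.shape
    if config.root is None:
        lo, hi = (pts.min(axis=0), pts.max(axis=0)) if n else (np.zeros(d), np.zeros(d))
        root = (lo + hi) / 2.0
    else:
        root = np.asarray(config.root, dtype=float)[:d]

    # tree arrays: index 0 is the root; targets are appended as attached
    coords = np.empty((n + 1, d))
    coords[0] = root
    parent = np.full(n + 1, -1, dtype=int)
    pathlen = np.zeros(n + 1)
    child_count = np.zeros(n + 1, dtype=int)
    target_of = np.full(n + 1, -1, dtype=int)  # original target index per tree node

    unconnected = np.arange(n)
    n_nodes = 1
    bf = config.bf
    for _ in range(n):
        eligible = np.flatnonzero(child_count[:n_nodes] < 2)
        dmat = cdist(pts[unconnected], coords[eligible])
        cost = dmat * (1.0 + bf) + bf * pathlen[eligible][None, :]
        ti, vi = np.unravel_index(np.argmin(cost), cost.shape)
        t = unconnected[ti]
        v = eligible[vi]
        coords[n_nodes] = pts[t]
        parent[n_nodes] = v
        pathlen[n_nodes] = pathlen[v] + dmat[ti, vi]
        child_count[v] += 1
        target_of[n_nodes] = t
        n_nodes += 1
        unconnected = np.delete(unconnected, ti)

    if d == 2:
        coords3 = np.column_stack([coords, np.zeros(n + 1)])
    else:
        coords3 = coords
    region = np.full(n + 1, 3, dtype=int)
    region[0] = 1
    return NeuronTree(
        ids=np.arange(1, n + 2),
        coords=coords3,
        radius=np.ones(n + 1),
        region=region,
        parent=parent,
    )


def euclidean_mst_oracle(points: PointCloud | np.ndarray) -> float:
    """Exact total length of the unconstrained Euclidean minimum spanning
    tree (independent reference for the bf = 0 greedy growth)."""
    pts = points.points if isinstance(points, PointCloud) else np.asarray(points, float)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    dmat = squareform(pdist(pts))
    mst = minimum_spanning_tree(dmat)
    return float(mst.sum())
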