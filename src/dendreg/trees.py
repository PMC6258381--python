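"""Neuronal reconstructions (SWC) and the point sets derived from them.

A reconstruction is a rooted geometric tree: every node carries a position in
micrometers, a radius, an integer structure code (SWC region), and a parent
link.  The regularity analysis operates on point clouds extracted from such
trees — branch points (nodes with two daughters) and termination points
(leaves) — so this module provides reading/writing of the standard 7-column
SWC text format, the preprocessing used before morphometry (dropping soma and
axon regions, re-joining fragments, resolving multifurcations into binary
cascades), and the point extraction itself.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NeuronTree",
    "PointCloud",
    "SwcParseError",
    "EmptyTreeError",
    "read_swc",
    "write_swc",
    "preprocess_tree",
    "extract_points",
]

#: SWC structure codes dropped before dendrite analysis: soma (1), axon (2),
#: and the two custom codes (5, 10) that archives use for non-dendritic parts.
DEFAULT_DROP_REGIONS = frozenset({1, 2, 5, 10})

#: Relative thickness below which a nominally 3D tree is treated as planar.
PLANARITY_RTOL = 1e-6


class SwcParseError(ValueError):
    """Raised when an SWC file cannot be interpreted as a single rooted tree."""


class EmptyTreeError(ValueError):
    """Raised when an operation would leave a tree without any nodes."""


@dataclass
class PointCloud:
    """A finite set of points in 2D or 3D Euclidean space (micrometers).

    Duplicate coordinates are permitted; they are meaningful for the
    regularity index (coincident points give a zero nearest-neighbor
    distance and hence R = 0).
    """

    points: np.ndarray
    dim: int = field(init=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim == 1:
            pts = pts.reshape(-1, 1) if pts.size else pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] not in (2, 3):
            raise ValueError(f"points must be (N, 2) or (N, 3), got {pts.shape}")
        if pts.size and not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        self.points = pts
        self.dim = int(pts.shape[1])

    @property
    def n(self) -> int:
        return int(self.points.shape[0])

    def __len__(self) -> int:
        return self.n

    def to_frame(self) -> pd.DataFrame:
        cols = ["x", "y", "z"][: self.dim]
        return pd.DataFrame(self.points, columns=cols)

    def to_table(self, path) -> None:
        """Write the cloud as headered tab-separated text (x, y[, z])."""
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_table(cls, path) -> "PointCloud":
        df = pd.read_csv(path, sep="\t")
        cols = [c for c in ("x", "y", "z") if c in df.columns]
        return cls(df[cols].to_numpy(dtype=float))


@dataclass
class NeuronTree:
    """A rooted binary(-izable) geometric tree in SWC coordinates.

    Nodes are stored in file order.  ``parent`` holds the *index* (not the
    SWC id) of each node's parent, with -1 marking the root.
    """

    ids: np.ndarray  # (n,) int SWC ids
    coords: np.ndarray  # (n, 3) float, micrometers
    radius: np.ndarray  # (n,) float
    region: np.ndarray  # (n,) int SWC structure codes
    parent: np.ndarray  # (n,) int index into arrays, -1 for root

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.radius = np.asarray(self.radius, dtype=float)
        self.region = np.asarray(self.region, dtype=int)
        self.parent = np.asarray(self.parent, dtype=int)

    @property
    def n_nodes(self) -> int:
        return int(self.ids.size)

    @property
    def root(self) -> int:
        """Index of the root node."""
        roots = np.flatnonzero(self.parent == -1)
        if roots.size != 1:
            raise SwcParseError(f"tree has {roots.size} roots, expected exactly 1")
        return int(roots[0])

    def child_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_nodes, dtype=int)
        np.add.at(counts, self.parent[self.parent >= 0], 1)
        return counts

    def children(self) -> list[list[int]]:
        """Per-node lists of child indices, in node (file) order."""
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                out[p].append(i)
        return out

    def validate(self) -> None:
        if self.n_nodes == 0:
            raise EmptyTreeError("tree has no nodes")
        _ = self.root
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("node coordinates must be finite")
        # acyclicity / single component: every node must reach the root
        order = topological_order(self)
        if order.size != self.n_nodes:
            raise SwcParseError("parent links do not form a single connected tree")


def topological_order(tree: NeuronTree) -> np.ndarray:
    """Node indices ordered root-first (parents before children)."""
    children = tree.children()
    try:
        root = tree.root
    except SwcParseError:
        return np.empty(0, dtype=int)
    order = []
    stack = [root]
    seen = np.zeros(tree.n_nodes, dtype=bool)
    while stack:
        i = stack.pop()
        if seen[i]:
            return np.empty(0, dtype=int)  # cycle
        seen[i] = True
        order.append(i)
        stack.extend(reversed(children[i]))
    return np.asarray(order, dtype=int)


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path) -> NeuronTree:
    """Read a standard 7-column SWC file into a :class:`NeuronTree`.

    Dialect: whitespace-separated columns (id, type, x, y, z, radius,
    parent), ``#`` comment lines, parent -1 marks the root.  Node order is
    preserved.  A malformed line, a parent id that references no node, or
    more than one root raises :class:`SwcParseError` naming the offending
    line.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.readlines()
    else:
        with open(path) as fh:
            lines = fh.readlines()

    rows = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SwcParseError(
                f"line {lineno}: expected 7 columns, got {len(parts)}: {raw.strip()!r}"
            )
        try:
            nid = int(parts[0])
            region = int(parts[1])
            x, y, z, r = (float(v) for v in parts[2:6])
            pid = int(parts[6])
        except ValueError as exc:
            raise SwcParseError(f"line {lineno}: {exc}") from exc
        rows.append((lineno, nid, region, x, y, z, r, pid))

    if not rows:
        raise SwcParseError("file contains no SWC records")

    ids = np.array([r[1] for r in rows], dtype=int)
    if np.unique(ids).size != ids.size:
        raise SwcParseError("duplicate node ids")
    id_to_index = {nid: i for i, nid in enumerate(ids)}

    parent = np.empty(len(rows), dtype=int)
    for i, (lineno, _nid, _reg, _x, _y, _z, _r, pid) in enumerate(rows):
        if pid == -1:
            parent[i] = -1
        elif pid in id_to_index:
            parent[i] = id_to_index[pid]
        else:
            raise SwcParseError(f"line {lineno}: parent id {pid} references no node")

    n_roots = int(np.sum(parent == -1))
    if n_roots != 1:
        raise SwcParseError(f"expected exactly 1 root, found {n_roots}")

    tree = NeuronTree(
        ids=ids,
        coords=np.array([[r[3], r[4], r[5]] for r in rows], dtype=float),
        radius=np.array([r[6] for r in rows], dtype=float),
        region=np.array([r[2] for r in rows], dtype=int),
        parent=parent,
    )
    tree.validate()
    return tree


def write_swc(tree: NeuronTree, path) -> None:
    """Write a tree as 7-column SWC; full float precision so a read/write
    round trip reproduces coordinates bit-exactly."""
    lines = ["# id type x y z radius parent\n"]
    for i in range(tree.n_nodes):
        pid = -1 if tree.parent[i] < 0 else int(tree.ids[tree.parent[i]])
        x, y, z = (float(c) for c in tree.coords[i])
        lines.append(
            f"{int(tree.ids[i])} {int(tree.region[i])} {x!r} {y!r} {z!r} "
            f"{float(tree.radius[i])!r} {pid}\n"
        )
    if isinstance(path, io.TextIOBase):
        path.writelines(lines)
    else:
        with open(path, "w") as fh:
            fh.writelines(lines)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _subset_tree(tree: NeuronTree, keep: np.ndarray) -> tuple[NeuronTree, np.ndarray]:
    """Restrict a tree to ``keep`` (bool mask); orphaned nodes become roots.

    Returns the (possibly multi-rooted) forest and the parent array where a
    node whose original parent was dropped gets parent -1.
    """
    idx = np.flatnonzero(keep)
    remap = -np.ones(tree.n_nodes, dtype=int)
    remap[idx] = np.arange(idx.size)
    new_parent = np.empty(idx.size, dtype=int)
    for new_i, old_i in enumerate(idx):
        p = tree.parent[old_i]
        new_parent[new_i] = remap[p] if (p >= 0 and keep[p]) else -1
    forest = NeuronTree(
        ids=tree.ids[idx],
        coords=tree.coords[idx],
        radius=tree.radius[idx],
        region=tree.region[idx],
        parent=new_parent,
    )
    return forest, new_parent


def _rejoin_fragments(forest: NeuronTree) -> NeuronTree:
    """Connect a multi-rooted forest into one tree.

    The main component is the one containing the lowest node id.  Remaining
    fragments are processed in increasing order of their root's node id;
    each orphaned fragment root is attached by a straight edge to the
    geometrically nearest node of the growing main component (ties broken
    by lowest node id).  This is a minimal-cable reconnection.
    """
    parent = forest.parent.copy()
    n = forest.n_nodes
    # label components
    comp = -np.ones(n, dtype=int)
    roots = np.flatnonzero(parent == -1)
    children: list[list[int]] = [[] for _ in range(n)]
    for i, p in enumerate(parent):
        if p >= 0:
            children[p].append(i)
    for c, r in enumerate(roots):
        stack = [int(r)]
        while stack:
            i = stack.pop()
            comp[i] = c
            stack.extend(children[i])
    if roots.size <= 1:
        return forest

    main_comp = comp[int(np.argmin(forest.ids))]
    in_main = comp == main_comp
    # fragment order: increasing root node id
    frag_comps = [c for c in range(roots.size) if c != main_comp]
    frag_comps.sort(key=lambda c: int(forest.ids[roots[c]]))

    for c in frag_comps:
        frag_root = int(roots[c])
        main_idx = np.flatnonzero(in_main)
        d = np.linalg.norm(forest.coords[main_idx] - forest.coords[frag_root], axis=1)
        best = np.min(d)
        cand = main_idx[d == best]
        attach_to = int(cand[np.argmin(forest.ids[cand])])
        parent[frag_root] = attach_to
        in_main |= comp == c

    return NeuronTree(
        ids=forest.ids,
        coords=forest.coords,
        radius=forest.radius,
        region=forest.region,
        parent=parent,
    )


def _split_multifurcations(tree: NeuronTree) -> NeuronTree:
    """Split every node with m > 2 children into a cascade of m-1 binary
    nodes at identical coordinates, children attached in input order.

    The inserted nodes inherit coordinates, radius and region; internal
    edges of the cascade have zero length.
    """
    ids = list(tree.ids)
    coords = list(tree.coords)
    radius = list(tree.radius)
    region = list(tree.region)
    parent = list(tree.parent)
    next_id = int(np.max(tree.ids)) + 1 if tree.n_nodes else 1

    children = tree.children()
    for node in range(tree.n_nodes):
        kids = children[node]
        current = node
        while len(kids) > 2:
            # keep the first child on `current`, push the rest one level down
            twin = len(ids)
            ids.append(next_id)
            next_id += 1
            coords.append(coords[current].copy() if hasattr(coords[current], "copy") else coords[current])
            radius.append(radius[current])
            region.append(region[current])
            parent.append(current)
            rest = kids[1:]
            for k in rest:
                parent[k] = twin
            kids = rest
            current = twin

    return NeuronTree(
        ids=np.asarray(ids, dtype=int),
        coords=np.asarray(coords, dtype=float),
        radius=np.asarray(radius, dtype=float),
        region=np.asarray(region, dtype=int),
        parent=np.asarray(parent, dtype=int),
    )


def preprocess_tree(tree: NeuronTree, drop_regions=DEFAULT_DROP_REGIONS) -> NeuronTree:
    """Sanitize a reconstruction for dendrite morphometry.

    Removes all nodes whose SWC region is in ``drop_regions`` (soma, axon and
    custom regions by default), re-joins the resulting fragments into a
    single tree by minimal-cable attachment, and resolves multifurcations so
    that every node has at most two children.  Idempotent.

    Raises :class:`EmptyTreeError` if nothing survives the deletion.
    """
    drop = set(drop_regions)
    keep = ~np.isin(tree.region, list(drop))
    if not np.any(keep):
        raise EmptyTreeError("preprocessing removed every node")
    forest, _ = _subset_tree(tree, keep)
    joined = _rejoin_fragments(forest)
    repaired = _split_multifurcations(joined)
    repaired.validate()
    return repaired


# ---------------------------------------------------------------------------
# Point extraction
# ---------------------------------------------------------------------------

def _planar_projection(coords: np.ndarray) -> np.ndarray | None:
    """Return 2D coordinates if the point set is essentially planar, else None.

    A set is treated as planar when its smallest principal-axis extent is
    below ``PLANARITY_RTOL`` times its largest; it is then projected onto
    the two dominant principal axes.
    """
    if coords.shape[0] < 3:
        return None
    centered = coords - coords.mean(axis=0)
    # principal axes via SVD of the centered coordinates
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] == 0:
        return None
    if s[-1] / s[0] < PLANARITY_RTOL:
        return centered @ vt[:2].T
    return None


def extract_points(tree: NeuronTree, which: str = "branch") -> PointCloud:
    """Extract branch, termination, continuation, or all node positions.

    Branch points are nodes with exactly two children; termination points
    are leaves; the root is never counted as either.  If the tree is planar
    (to within numerical tolerance) the cloud is returned in 2D, projected
    onto the two dominant principal axes.
    """
    counts = tree.child_counts()
    root = tree.root
    not_root = np.arange(tree.n_nodes) != root
    if which == "branch":
        mask = (counts == 2) & not_root
    elif which == "termination":
        mask = (counts == 0) & not_root
    elif which == "continuation":
        mask = (counts == 1) & not_root
    elif which == "all":
        mask = np.ones(tree.n_nodes, dtype=bool)
    else:
        raise ValueError(f"unknown point class {which!r}")

    planar = _planar_projection(tree.coords)
    coords = planar if planar is not None else tree.coords
    return PointCloud(coords[mask])
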