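import numpy as np
import pytest

from dendreg import NeuronTree


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# 7-node full binary tree: root 1 -> (2, 3), 2 -> (4, 5), 3 -> (6, 7)
BINARY7_SWC = """\
# full binary tree
1 1 0 0 0 1 -1
2 3 -1 1 0 1 1
3 3 1 1 0 1 1
4 3 -2 2 0 1 2
5 3 -0.5 2 0 1 2
6 3 0.5 2 0 1 3
7 3 2 2 0 1 3
"""


@pytest.fixture
def binary7(tmp_path):
    path = tmp_path / "binary7.swc"
    path.write_text(BINARY7_SWC)
    return path


def build_tree(coords, parent, region=None, ids=None):
    """Small helper: NeuronTree from plain lists (3D-padded coordinates)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[1] == 2:
        coords = np.column_stack([coords, np.zeros(len(coords))])
    n = len(coords)
    return NeuronTree(
        ids=np.arange(1, n + 1) if ids is None else np.asarray(ids),
        coords=coords,
        radius=np.ones(n),
        region=np.full(n, 3) if region is None else np.asarray(region),
        parent=np.asarray(parent, dtype=int),
    )


def degree_compatible_instance(rng, n_range=(5, 11), dim=3, max_tries=200):
    """Random points whose Euclidean MST fits the binary growth constraint:
    every node has MST degree <= 3 and the first point (used as the root,
    which may take at most 2 children) has degree <= 2."""
    from scipy.sparse.csgraph import minimum_spanning_tree
    from scipy.spatial.distance import pdist, squareform

    for _ in range(max_tries):
        n = int(rng.integers(*n_range))
        pts = rng.uniform(0, 100, (n, dim))
        mst = minimum_spanning_tree(squareform(pdist(pts))).tocoo()
        deg = np.zeros(n, dtype=int)
        for i, j in zip(mst.row, mst.col):
            deg[i] += 1
            deg[j] += 1
        if deg.max() <= 3 and deg[0] <= 2:
            return pts
    raise RuntimeError("no degree-compatible instance found")


def random_binary_tree(rng, n_splits=10):
    """Random geometric binary tree: a root with a single stem, grown by
    repeatedly splitting a random leaf into two daughters."""
    coords = [np.zeros(3), rng.normal(size=3)]
    parent = [-1, 0]
    leaves = [1]
    for _ in range(n_splits):
        leaf = leaves.pop(int(rng.integers(len(leaves))))
        for _ in range(2):
            coords.append(coords[leaf] + rng.normal(size=3))
            parent.append(leaf)
            leaves.append(len(coords) - 1)
    return build_tree(np.asarray(coords), parent)
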