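import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dendreg import (
    EmptyTreeError,
    SwcParseError,
    extract_points,
    preprocess_tree,
    read_swc,
    write_swc,
)
from dendreg.trees import PointCloud

from conftest import build_tree, random_binary_tree


class TestReadSwc:
    def test_minimal_chain(self, tmp_path):
        p = tmp_path / "chain.swc"
        p.write_text("1 1 0 0 0 1 -1\n2 3 0 1 0 1 1\n3 3 0 2 0 1 2\n")
        tree = read_swc(p)
        assert tree.n_nodes == 3
        assert tree.ids[tree.root] == 1

    def test_binary7_child_counts(self, binary7):
        tree = read_swc(binary7)
        counts = tree.child_counts()
        assert sorted(counts.tolist(), reverse=True) == [2, 2, 2, 0, 0, 0, 0]

    @pytest.mark.parametrize(
        "text,match",
        [
            ("1 1 0 0 0 1 -1\n2 3 0 1 0 1 99\n", "parent id 99"),
            ("1 1 0 0 0 1 -1\n2 3 0 1 0\n", "7 columns"),
            ("1 1 0 0 0 1 -1\n2 3 0 1 0 1 -1\n", "root"),
            ("", "no SWC records"),
        ],
    )
    def test_malformed_inputs(self, tmp_path, text, match):
        p = tmp_path / "bad.swc"
        p.write_text(text)
        with pytest.raises(SwcParseError, match=match):
            read_swc(p)


class TestRoundTrip:
    def test_topology_and_regions(self, binary7, tmp_path):
        tree = read_swc(binary7)
        out = tmp_path / "out.swc"
        write_swc(tree, out)
        back = read_swc(out)
        np.testing.assert_array_equal(tree.parent, back.parent)
        np.testing.assert_array_equal(tree.region, back.region)
        np.testing.assert_array_equal(tree.ids, back.ids)

    def test_full_precision_coordinates(self, rng):
        tree = random_binary_tree(rng, n_splits=50)
        buf = io.StringIO()
        write_swc(tree, buf)
        buf.seek(0)
        back = read_swc(buf)
        np.testing.assert_array_equal(tree.coords, back.coords)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(1, 12), st.integers(0, 2**31 - 1))
    def test_roundtrip_random_trees(self, n_splits, seed):
        rng = np.random.default_rng(seed)
        tree = random_binary_tree(rng, n_splits=n_splits)
        buf = io.StringIO()
        write_swc(tree, buf)
        buf.seek(0)
        back = read_swc(buf)
        np.testing.assert_array_equal(tree.coords, back.coords)
        np.testing.assert_array_equal(tree.parent, back.parent)


class TestPreprocess:
    def test_identity_when_nothing_to_drop(self, binary7):
        tree = read_swc(binary7)
        tree.region[:] = 3
        out = preprocess_tree(tree)
        assert out.n_nodes == tree.n_nodes
        np.testing.assert_array_equal(out.parent, tree.parent)

    def test_trifurcation_split_adds_branch_point(self):
        # root -> stem -> 3 children: the stem must split into two stacked BPs
        coords = [[0, 0], [0, 1], [-1, 2], [0, 2], [1, 2]]
        tree = build_tree(coords, [-1, 0, 1, 1, 1])
        out = preprocess_tree(tree, drop_regions=set())
        counts = out.child_counts()
        assert counts.max() == 2
        n_bp_before = 1  # one multifurcation
        n_bp_after = int(np.sum(counts == 2))
        assert n_bp_after == n_bp_before + 1
        # the inserted node sits at identical coordinates
        assert out.n_nodes == tree.n_nodes + 1

    def test_soma_drop_reroots_chain(self):
        tree = build_tree([[0, 0], [0, 1], [0, 2]], [-1, 0, 1], region=[1, 3, 3])
        out = preprocess_tree(tree, drop_regions={1})
        assert out.n_nodes == 2
        assert out.ids[out.root] == 2

    def test_fragment_rejoin_to_nearest(self):
        # soma between two dendrite fragments; fragment 2's root must attach
        # to the geometrically nearest surviving node
        coords = [[0, 0], [0, 1], [0, 2], [0, 2.5], [5, 0]]
        region = [3, 1, 3, 3, 3]
        tree = build_tree(coords, [-1, 0, 1, 2, 0], region=region)
        out = preprocess_tree(tree, drop_regions={1})
        out.validate()
        assert out.n_nodes == 4
        # node id 3 (fragment root) re-attached to node id 1? nearest of
        # {id1 at (0,0), id5 at (5,0)} to (0,2) is id1
        i3 = int(np.flatnonzero(out.ids == 3)[0])
        assert out.ids[out.parent[i3]] == 1

    def test_empty_after_drop_raises(self):
        tree = build_tree([[0, 0]], [-1], region=[1])
        with pytest.raises(EmptyTreeError):
            preprocess_tree(tree, drop_regions={1})

    def test_idempotent(self, rng):
        coords = rng.normal(size=(9, 3))
        parent = [-1, 0, 1, 1, 1, 1, 0, 6, 6]  # node 1 has 4 children
        tree = build_tree(coords, parent)
        once = preprocess_tree(tree, drop_regions=set())
        twice = preprocess_tree(once, drop_regions=set())
        assert once.n_nodes == twice.n_nodes
        np.testing.assert_array_equal(once.parent, twice.parent)


class TestExtractPoints:
    def test_balanced_tree_counts(self, binary7):
        tree = read_swc(binary7)
        # root has 2 children but is never a BP; 2 & 3 are BPs; 4 leaves
        assert extract_points(tree, "branch").n == 2
        assert extract_points(tree, "termination").n == 4

    def test_unbranched_chain(self):
        tree = build_tree([[0, 0], [0, 1], [0, 2]], [-1, 0, 1])
        assert extract_points(tree, "branch").n == 0
        assert extract_points(tree, "termination").n == 1

    def test_tp_equals_bp_plus_one_on_random_binary_trees(self, rng):
        # binary-tree identity for trees whose root carries a single stem
        for _ in range(20):
            tree = random_binary_tree(rng, n_splits=int(rng.integers(1, 15)))
            b = extract_points(tree, "branch").n
            t = extract_points(tree, "termination").n
            assert t == b + 1

    def test_planar_tree_projects_to_2d(self, rng):
        tree = random_binary_tree(rng, n_splits=8)
        tree.coords[:, 2] = 0.0  # flatten
        cloud = extract_points(tree, "all")
        assert cloud.dim == 2

    def test_3d_tree_stays_3d(self, rng):
        tree = random_binary_tree(rng, n_splits=8)
        assert extract_points(tree, "all").dim == 3


class TestPointCloud:
    def test_table_roundtrip(self, tmp_path, rng):
        cloud = PointCloud(rng.uniform(size=(30, 3)))
        p = tmp_path / "cloud.tsv"
        cloud.to_table(p)
        back = PointCloud.from_table(p)
        assert back.dim == 3
        np.testing.assert_allclose(back.points, cloud.points)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            PointCloud(np.array([[0.0, np.nan]]))
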