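import numpy as np
import pytest

from dendreg import (
    PointCloud,
    RegularityIndex,
    csr_test,
    estimate_R_mc,
    expected_nn_analytic,
    make_fixtures,
    mean_nn_distance,
    nn_distances,
    sample_uniform_in_hull,
    tight_hull,
    volume_correct,
)


class TestMeanNN:
    def test_two_points(self):
        assert mean_nn_distance(PointCloud(np.array([[0, 0], [3, 4]], float))) == 5.0

    def test_three_collinear(self):
        cloud = PointCloud(np.array([[0, 0], [1, 0], [3, 0]], float))
        assert mean_nn_distance(cloud) == pytest.approx(4 / 3)

    def test_duplicates_give_zero(self):
        cloud, _ = make_fixtures("duplicated_pairs", {"n": 50}, seed=1)
        assert mean_nn_distance(cloud) == 0.0

    def test_single_point_raises(self):
        with pytest.raises(ValueError):
            nn_distances(np.array([[0.0, 0.0]]))


class TestAnalyticExpectation:
    @pytest.mark.parametrize(
        "rho,dim,expected",
        [
            (1.0, 2, 0.5),
            (4.0, 2, 0.25),
            (1.0, 3, 0.5539602783650901),  # Gamma(4/3) (4 pi / 3)^(-1/3)
        ],
    )
    def test_closed_forms(self, rho, dim, expected):
        assert expected_nn_analytic(rho, dim) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_density_raises(self):
        with pytest.raises(ValueError):
            expected_nn_analytic(0.0, 2)


@pytest.fixture(scope="module")
def square_hull():
    cloud, _ = make_fixtures("poisson", {"n": 800}, seed=21)
    return tight_hull(cloud)


class TestHullSampling:
    def test_all_points_inside(self, square_hull, rng):
        sample = sample_uniform_in_hull(square_hull, 500, rng)
        assert square_hull.contains(sample.points, tol=1e-7).all()

    def test_quadrant_balance(self, square_hull):
        rng = np.random.default_rng(5)
        sample = sample_uniform_in_hull(square_hull, 1000, rng).points
        counts = [
            np.sum((sample[:, 0] < 0.5) & (sample[:, 1] < 0.5)),
            np.sum((sample[:, 0] >= 0.5) & (sample[:, 1] < 0.5)),
            np.sum((sample[:, 0] < 0.5) & (sample[:, 1] >= 0.5)),
            np.sum((sample[:, 0] >= 0.5) & (sample[:, 1] >= 0.5)),
        ]
        # chi-square sanity bound: each quadrant ~ 250, sd ~ 13.7
        assert max(abs(c - 250) for c in counts) < 70

    def test_same_seed_identical(self, square_hull):
        a = sample_uniform_in_hull(square_hull, 100, np.random.default_rng(3)).points
        b = sample_uniform_in_hull(square_hull, 100, np.random.default_rng(3)).points
        np.testing.assert_array_equal(a, b)


class TestVolumeCorrection:
    def test_already_matching_is_identity(self):
        cloud, _ = make_fixtures("poisson", {"n": 300}, seed=9)
        v = tight_hull(cloud).measure
        out = volume_correct(cloud, v)
        np.testing.assert_array_equal(out.points, cloud.points)

    def test_target_8x_in_3d_stretches_2x(self):
        cloud, _ = make_fixtures("poisson", {"n": 300, "dim": 3}, seed=10)
        v = tight_hull(cloud).measure
        out = volume_correct(cloud, 8.0 * v, q=0.5)
        centroid = cloud.points.mean(axis=0)
        ratio = (out.points - centroid) / (cloud.points - centroid)
        assert np.allclose(ratio, 2.0, rtol=1e-6)

    def test_nn_distance_scales_with_coordinates(self):
        cloud, _ = make_fixtures("poisson", {"n": 300}, seed=11)
        v = tight_hull(cloud).measure
        out = volume_correct(cloud, 4.0 * v)
        assert mean_nn_distance(out) == pytest.approx(2.0 * mean_nn_distance(cloud), rel=1e-9)


class TestEstimateR:
    def test_duplicated_pairs_r_zero(self):
        cloud, _ = make_fixtures("duplicated_pairs", {"n": 50}, seed=12)
        est = estimate_R_mc(cloud, m=50, rng=0)
        assert est.r == 0.0
        assert est.r0_mean == 0.0
        assert est.re_mean > 0

    def test_all_coincident_degenerate_flag(self):
        cloud = PointCloud(np.zeros((10, 2)))
        with pytest.warns(UserWarning):
            est = estimate_R_mc(cloud, m=10, rng=0)
        assert est.r == 0.0
        assert est.degenerate_hull

    def test_single_poisson_cloud_near_one(self):
        cloud, _ = make_fixtures("poisson", {"n": 1000}, seed=13)
        est = estimate_R_mc(cloud, m=100, rng=1)
        assert est.r == pytest.approx(1.0, abs=0.12)
        assert est.ci_low <= est.ci_high

    def test_triangular_lattice_interior_matches_analytic(self):
        cloud, meta = make_fixtures("triangular_lattice", {"rows": 40, "cols": 40})
        pts = cloud.points
        s = meta["spacing"]
        lo, hi = pts.min(0), pts.max(0)
        interior = np.all((pts > lo + 2 * s) & (pts < hi - 2 * s), axis=1)
        r0 = nn_distances(pts)[interior].mean()
        r = r0 / expected_nn_analytic(meta["density"], 2)
        assert r == pytest.approx(meta["true_r"], abs=1e-9)

    def test_determinism_bit_identical(self):
        cloud, _ = make_fixtures("poisson", {"n": 100}, seed=14)
        a = estimate_R_mc(cloud, m=20, rng=7)
        b = estimate_R_mc(cloud, m=20, rng=7)
        assert a.r == b.r
        assert a.ci_low == b.ci_low
        np.testing.assert_array_equal(a.re_samples, b.re_samples)

    def test_scale_invariance_same_seed(self):
        # doubling coordinates (a power of two) rescales every internal
        # quantity exactly, so R is reproduced bit-for-bit
        cloud, _ = make_fixtures("poisson", {"n": 200}, seed=15)
        a = estimate_R_mc(cloud, m=20, rng=3)
        b = estimate_R_mc(PointCloud(cloud.points * 2.0), m=20, rng=3)
        assert b.r == pytest.approx(a.r, rel=1e-12)
        assert b.r0_mean == pytest.approx(2.0 * a.r0_mean, rel=1e-12)

    def test_translation_invariance_same_seed(self):
        cloud, _ = make_fixtures("poisson", {"n": 200}, seed=16)
        a = estimate_R_mc(cloud, m=20, rng=4)
        b = estimate_R_mc(PointCloud(cloud.points + 100.0), m=20, rng=4)
        assert b.r == pytest.approx(a.r, rel=1e-9)

    def test_fewer_than_two_points_raises(self):
        with pytest.raises(ValueError):
            estimate_R_mc(PointCloud(np.zeros((1, 2))))

    def test_dispersion_ordering(self):
        # duplicated pairs < clustered < Poisson < lattice
        dup, _ = make_fixtures("duplicated_pairs", {"n": 50, "side": 200.0}, seed=17)
        clus, _ = make_fixtures("known_r", {"n": 50, "target_r": 0.5}, seed=18)
        poisson, _ = make_fixtures("poisson", {"n": 50, "side": 200.0}, seed=19)
        lattice, _ = make_fixtures("square_lattice", {"rows": 8, "cols": 8, "spacing": 25.0})
        rs = [estimate_R_mc(c, m=50, rng=i).r for i, c in enumerate([dup, clus, poisson, lattice])]
        assert rs[0] == 0.0
        assert rs[0] < rs[1] < rs[2] < rs[3]


class TestModelInterface:
    def test_fit_matches_function(self):
        cloud, _ = make_fixtures("poisson", {"n": 100}, seed=20)
        res = RegularityIndex(cloud, mc_iterations=20).fit(seed=5)
        fn = estimate_R_mc(cloud, m=20, rng=5)
        assert res.r == fn.r

    def test_from_dataframe_and_summary(self):
        cloud, _ = make_fixtures("poisson", {"n": 60}, seed=21)
        model = RegularityIndex.from_dataframe(cloud.to_frame(), mc_iterations=20)
        res = model.fit(seed=1)
        text = res.summary()
        assert "R = r0/rE" in text
        assert f"{res.n_points:d}" in text
        frame = res.to_frame()
        assert frame.loc[0, "r"] == res.r

    def test_from_tree(self, rng):
        from conftest import random_binary_tree

        tree = random_binary_tree(rng, n_splits=30)
        res = RegularityIndex.from_tree(tree, "termination", mc_iterations=20).fit(seed=2)
        assert res.r > 0


class TestCsr:
    def test_duplicated_pairs_minimum_p(self):
        cloud, _ = make_fixtures("duplicated_pairs", {"n": 50}, seed=22)
        t = csr_test(cloud, m=99, rng=1)
        assert t.p_clustered == pytest.approx(1 / 100)
        assert t.p_regular == 1.0
        assert t.p_two_sided == pytest.approx(2 / 100)

    def test_lattice_detected_as_regular(self):
        cloud, _ = make_fixtures("square_lattice", {"rows": 15, "cols": 15})
        t = csr_test(cloud, m=99, rng=2)
        assert t.p_regular <= 0.05
        assert t.p_clustered > 0.5

    def test_type_one_error_rate(self):
        # two-sided rejections at the 5% level over 100 Poisson clouds
        rejections = 0
        for i in range(100):
            cloud, _ = make_fixtures("poisson", {"n": 50}, seed=3000 + i)
            t = csr_test(cloud, m=99, rng=4000 + i)
            rejections += t.p_two_sided < 0.05
        assert rejections <= 12  # ~5 expected; binomial(100, .05) upper tail

    def test_p_value_consistency(self):
        cloud, _ = make_fixtures("poisson", {"n": 80}, seed=23)
        t = csr_test(cloud, m=49, rng=3)
        assert 0 < t.p_clustered <= 1 and 0 < t.p_regular <= 1
        assert min(t.p_clustered, t.p_regular) <= t.p_two_sided
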