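"""Ward clustering and stopping-rule diagnostics against coordinate oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import worklife as wl
from worklife.sequences import DistanceMatrix

from conftest import naive_ward_merges


def euclid_dm(points):
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    return DistanceMatrix(condensed=pdist(points), ids=np.arange(len(points))), points


class TestWardLinkage:
    def test_two_points_single_merge(self):
        dm, _ = euclid_dm([0.0, 3.0])
        tree = wl.ward_linkage(dm)
        assert tree.merges.shape == (1, 4)
        assert tree.merges[0, 2] == pytest.approx(3.0)

    def test_four_point_example(self):
        dm, _ = euclid_dm([0.0, 0.1, 10.0, 10.1])
        tree = wl.ward_linkage(dm)
        # first two merges join the close pairs
        first = {int(tree.merges[0, 0]), int(tree.merges[0, 1])}
        second = {int(tree.merges[1, 0]), int(tree.merges[1, 1])}
        assert {frozenset(first), frozenset(second)} == {
            frozenset({0, 1}),
            frozenset({2, 3}),
        }
        labels = wl.cut_tree(tree, 2)
        assert labels[0] == labels[1] != labels[2]
        assert labels[2] == labels[3]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_coordinate_ward_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(18, 2))
        dm, _ = euclid_dm(pts)
        tree = wl.ward_linkage(dm)
        oracle = naive_ward_merges(pts)
        # compare member sets and Ward.D2 heights merge by merge
        leaves = {i: {i} for i in range(18)}
        for row, (members, height) in zip(tree.merges, oracle):
            a, b = int(row[0]), int(row[1])
            merged = leaves[a] | leaves[b]
            leaves[len(leaves)] = merged
            assert merged == set(members)
            assert row[2] == pytest.approx(height, abs=1e-8)

    def test_monotone_heights_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            pts = rng.normal(size=(30, 3))
            tree = wl.ward_linkage(euclid_dm(pts)[0])
            assert (np.diff(tree.merges[:, 2]) >= -1e-9).all()

    def test_ward_d_variant_is_valid_and_separates_blobs(self):
        rng = np.random.default_rng(1)
        pts = np.concatenate([rng.normal(0, 0.1, 6), rng.normal(9, 0.1, 6)])
        dm = euclid_dm(pts)[0]
        td = wl.ward_linkage(dm, variant="d")
        assert (np.diff(td.merges[:, 2]) >= -1e-9).all()
        labels = wl.cut_tree(td, 2)
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[-1]

    def test_invalid_variant(self):
        dm, _ = euclid_dm([0.0, 1.0])
        with pytest.raises(ValueError):
            wl.ward_linkage(dm, variant="median")


class TestCutTree:
    def test_extreme_cuts(self):
        dm, _ = euclid_dm(np.arange(6.0))
        tree = wl.ward_linkage(dm)
        assert len(set(wl.cut_tree(tree, 1))) == 1
        assert len(set(wl.cut_tree(tree, 6))) == 6
        with pytest.raises(ValueError):
            wl.cut_tree(tree, 0)
        with pytest.raises(ValueError):
            wl.cut_tree(tree, 7)

    def test_partitions_are_nested(self):
        rng = np.random.default_rng(2)
        tree = wl.ward_linkage(euclid_dm(rng.normal(size=(40, 2)))[0])
        prev = wl.cut_tree(tree, 2)
        for k in range(3, 10):
            cur = wl.cut_tree(tree, k)
            # every cluster at k sits inside exactly one cluster at k-1
            for c in np.unique(cur):
                parents = np.unique(prev[cur == c])
                assert len(parents) == 1
            prev = cur

    def test_labels_deterministic_by_size(self):
        dm, _ = euclid_dm([0.0, 0.1, 0.2, 10.0, 10.1])
        tree = wl.ward_linkage(dm)
        labels = wl.cut_tree(tree, 2)
        assert labels.tolist() == [1, 1, 1, 2, 2]  # larger cluster first


class TestCalinskiHarabasz:
    def test_perfect_partition_infinite(self):
        dm, _ = euclid_dm([0.0, 0.0, 5.0, 5.0])
        assert wl.ch_pseudo_f(dm, np.array([1, 1, 2, 2])) == np.inf

    @pytest.mark.parametrize("seed", [0, 3])
    def test_matches_variance_oracle_on_euclidean_data(self, seed):
        from sklearn.metrics import calinski_harabasz_score

        rng = np.random.default_rng(seed)
        pts = np.vstack([rng.normal(0, 1, (30, 2)), rng.normal(5, 1, (25, 2))])
        labels = np.repeat([1, 2], [30, 25])
        dm, _ = euclid_dm(pts)
        ours = wl.ch_pseudo_f(dm, labels)
        ref = calinski_harabasz_score(pts, labels)
        assert ours == pytest.approx(ref, rel=1e-8)

    def test_structure_beats_random_labels(self):
        rng = np.random.default_rng(4)
        # random labels on structureless data: F fluctuates around 1
        blob = rng.normal(size=(200, 2))
        f_rand = wl.ch_pseudo_f(euclid_dm(blob)[0], rng.integers(1, 3, size=200))
        assert f_rand == pytest.approx(1.0, abs=0.9)
        # true labels on clustered data: far larger
        pts = np.vstack([rng.normal(0, 1, (100, 2)), rng.normal(8, 1, (100, 2))])
        f_true = wl.ch_pseudo_f(euclid_dm(pts)[0], np.repeat([1, 2], 100))
        assert f_true > 100 * f_rand

    def test_invalid_partitions(self):
        dm, _ = euclid_dm([0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            wl.ch_pseudo_f(dm, np.array([1, 1, 1]))
        with pytest.raises(ValueError):
            wl.ch_pseudo_f(dm, np.array([1, 2, 3]))


class TestDudaHart:
    def test_singleton_split_of_two_points(self):
        dm, _ = euclid_dm([0.0, 4.0])
        ratio, t2 = wl.duda_hart(dm, [0, 1], [0], [1])
        assert ratio == 0.0 and t2 == np.inf

    def test_matches_coordinate_oracle(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(6, 1, (15, 2))])
        dm, _ = euclid_dm(pts)
        parent = np.arange(35)
        left, right = np.arange(20), np.arange(20, 35)
        ratio, t2 = wl.duda_hart(dm, parent, left, right)

        def sse(x):
            return ((x - x.mean(axis=0)) ** 2).sum()

        je1 = sse(pts)
        je2 = sse(pts[:20]) + sse(pts[20:])
        assert ratio == pytest.approx(je2 / je1, rel=1e-8)
        assert t2 == pytest.approx((je1 - je2) / (je2 / 33), rel=1e-8)
        # a split between two tight blobs: ratio well below 1, large T^2
        assert ratio < 0.5 and t2 > 30

    def test_ratio_t2_algebraic_identity(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(24, 2))
        dm, _ = euclid_dm(pts)
        parent = np.arange(24)
        ratio, t2 = wl.duda_hart(dm, parent, np.arange(10), np.arange(10, 24))
        assert t2 == pytest.approx((1 / ratio - 1) * (24 - 2), rel=1e-10)

    def test_degenerate_split_rejected(self):
        dm, _ = euclid_dm([0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            wl.duda_hart(dm, [0, 1, 2], [0, 1, 2], [])


class TestDiagnostics:
    def test_single_k_table(self):
        dm, _ = euclid_dm([0.0, 0.1, 10.0, 10.1])
        tree = wl.ward_linkage(dm)
        diag = wl.diagnostics_table(tree, dm, k_range=[2])
        assert len(diag) == 1 and diag["k"].iloc[0] == 2

    def test_empty_range_rejected(self):
        dm, _ = euclid_dm([0.0, 1.0, 2.0])
        tree = wl.ward_linkage(dm)
        with pytest.raises(ValueError):
            wl.diagnostics_table(tree, dm, k_range=[])

    def test_blob_recommendation_flagged_low_confidence(self):
        rng = np.random.default_rng(8)
        dm, _ = euclid_dm(rng.normal(size=(80, 2)))
        tree = wl.ward_linkage(dm)
        diag = wl.diagnostics_table(tree, dm, range(2, 9))
        _, note = wl.recommend_k(diag)
        # a single Gaussian blob has a monotone CH curve
        if not any(
            diag["ch_pseudo_f"].iloc[i] >= diag["ch_pseudo_f"].iloc[i - 1]
            and diag["ch_pseudo_f"].iloc[i] >= diag["ch_pseudo_f"].iloc[i + 1]
            for i in range(1, len(diag) - 1)
        ):
            assert "low confidence" in note

    def test_user_k_never_overridden(self):
        dm, _ = euclid_dm([0.0, 0.1, 10.0, 10.1, 20.0, 20.1])
        tree = wl.ward_linkage(dm)
        sol = wl.cluster_solution(tree, dm, k=2, k_range=range(2, 5))
        assert sol.k == 2 and "user-specified" in sol.rationale


class TestStateDistribution:
    def test_point_mass_rows_and_normalization(self, small_bundle):
        panel = small_bundle.sequences
        labels = np.ones(panel.n, dtype=int)
        dist = wl.state_distribution(panel, labels)
        sums = dist.groupby(["cluster", "age"])["proportion"].sum()
        assert np.allclose(sums, 1.0)

    def test_stable_cluster_is_st_dominated(self, small_bundle):
        truth = small_bundle.truth.to_numpy()
        labels = (truth == "stable_st").astype(int) + 1
        dist = wl.state_distribution(small_bundle.sequences, labels)
        stable = dist[(dist["cluster"] == 2) & (dist["state"] == "ST")]
        assert (stable["proportion"] >= 0.8).all()

    def test_label_mismatch_rejected(self, small_bundle):
        with pytest.raises(ValueError):
            wl.state_distribution(small_bundle.sequences, np.array([1, 2]))
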