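"""Filter-stage tests, each checked against a brute-force oracle where the
operation has one (box membership, O(n²) DBSCAN, k-NN statistics)."""

import numpy as np
import pytest

from bovimetry.geometry import PointCloud
from bovimetry.preprocess import (
    CropBox,
    FilterParams,
    dbscan_cluster,
    passthrough_crop,
    select_target_cluster,
    sor_mean_knn_distance,
    statistical_outlier_removal,
)

# ---------------------------------------------------------------- oracles


def brute_dbscan(points, r, N):
    """Textbook O(n²) density clustering: core points by closed-ball count,
    clusters as density-connected components, border points attached to the
    first core cluster reaching them in scan order."""
    n = len(points)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    neighbors = [np.where(d[i] < r)[0] for i in range(n)]
    core = np.array([len(nb) >= N for nb in neighbors])
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        labels[i] = cluster
        frontier = [i]
        while frontier:
            j = frontier.pop(0)
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                    if core[k]:
                        frontier.append(k)
        cluster += 1
    return labels


def brute_sor_removed(points, k, alpha):
    """Brute-force mean k-NN distance per point, then the global criterion."""
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    mu = np.sort(d, axis=1)[:, :k].mean(axis=1)
    return set(np.where(mu > mu.mean() + alpha * mu.std())[0])


def same_partition(a, b):
    """Equal clusterings up to label renaming (noise label fixed at -1)."""
    a, b = np.asarray(a), np.asarray(b)
    if not np.array_equal(a == -1, b == -1):
        return False
    mapping = {}
    for la, lb in zip(a, b):
        if la == -1:
            continue
        if mapping.setdefault(la, lb) != lb:
            return False
    return len(set(mapping.values())) == len(mapping)


# ---------------------------------------------------------------- crop


class TestPassthroughCrop:
    def test_enclosing_box_is_identity(self, random_cloud):
        box = CropBox((-100, -100, -100), (100, 100, 100))
        np.testing.assert_array_equal(
            passthrough_crop(random_cloud, box).points, random_cloud.points
        )

    def test_disjoint_box_empties_cloud(self, random_cloud):
        box = CropBox((100, 100, 100), (101, 101, 101))
        with pytest.warns(UserWarning, match="empty"):
            assert len(passthrough_crop(random_cloud, box)) == 0

    def test_membership_matches_brute_force(self, rng):
        pts = rng.uniform(-1.5, 1.5, (10, 3))
        box = CropBox((0, 0, 0), (1, 1, 1))
        got = passthrough_crop(PointCloud(pts), box).points
        expected = [p for p in pts if all(0 <= c <= 1 for c in p)]
        np.testing.assert_array_equal(got, np.array(expected).reshape(-1, 3))

    def test_idempotent(self, random_cloud):
        box = CropBox((-0.5, -0.5, -0.5), (0.5, 0.5, 0.5))
        once = passthrough_crop(random_cloud, box)
        twice = passthrough_crop(once, box)
        np.testing.assert_array_equal(once.points, twice.points)

    def test_invalid_box_rejected(self):
        with pytest.raises(ValueError, match="min"):
            CropBox((0, 0, 0), (1, -1, 1))


# ---------------------------------------------------------------- dbscan


class TestDbscanCluster:
    def test_single_blob_single_cluster(self, rng):
        cloud = PointCloud(rng.normal(0, 0.01, (50, 3)))
        out = dbscan_cluster(cloud, r=0.1, N=1)
        assert set(out.labels) == {0}

    def test_isolated_points_are_noise(self):
        pts = np.diag([10.0, 20.0, 30.0])
        out = dbscan_cluster(PointCloud(pts), r=0.1, N=2)
        assert set(out.labels) == {-1}

    def test_two_blobs_match_brute_force(self, rng):
        a = rng.normal((0, 0, 0), 0.02, (120, 3))
        b = rng.normal((1, 0, 0), 0.02, (80, 3))
        stray = rng.uniform(2, 3, (10, 3))
        pts = np.vstack([a, b, stray])
        out = dbscan_cluster(PointCloud(pts), r=0.1, N=5)
        expected = brute_dbscan(pts, 0.1, 5)
        assert same_partition(out.labels, expected)

    def test_permutation_invariant_up_to_relabel(self, rng):
        pts = np.vstack(
            [rng.normal((0, 0, 0), 0.02, (60, 3)), rng.normal((1, 1, 0), 0.02, (60, 3))]
        )
        perm = rng.permutation(len(pts))
        l1 = dbscan_cluster(PointCloud(pts), 0.1, 5).labels
        l2 = dbscan_cluster(PointCloud(pts[perm]), 0.1, 5).labels
        assert same_partition(l1[perm], l2)

    def test_empty_cloud_raises(self):
        with pytest.raises(ValueError, match="empty"):
            dbscan_cluster(PointCloud(np.empty((0, 3))), 0.1, 5)


# ---------------------------------------------------------------- target cluster


class TestSelectTargetCluster:
    def test_single_cluster_returned(self, rng):
        cloud = PointCloud(rng.normal(size=(30, 3)), labels=np.zeros(30, dtype=int))
        assert len(select_target_cluster(cloud)) == 30

    def test_extent_score_prefers_cattle_sized_cluster(self, rng):
        big = rng.uniform(0, 1, (100, 3)) * np.array([2.0, 0.8, 1.3])
        small = rng.uniform(0, 1, (100, 3)) * 0.3 + 5.0
        pts = np.vstack([big, small])
        labels = np.r_[np.zeros(100, int), np.ones(100, int)]
        out = select_target_cluster(PointCloud(pts, labels=labels), (2.0, 0.7, 1.4))
        np.testing.assert_array_equal(out.points, big)

    def test_only_noise_raises(self):
        cloud = PointCloud(np.zeros((5, 3)), labels=-np.ones(5, dtype=int))
        with pytest.raises(ValueError, match="no target cluster"):
            select_target_cluster(cloud)

    def test_unlabelled_cloud_raises(self, random_cloud):
        with pytest.raises(ValueError, match="labels"):
            select_target_cluster(random_cloud)


# ---------------------------------------------------------------- SOR


class TestStatisticalOutlierRemoval:
    def test_huge_alpha_removes_nothing(self, random_cloud):
        out = statistical_outlier_removal(random_cloud, k=8, alpha=1e6)
        assert len(out) == len(random_cloud)

    def test_far_point_removed_matching_brute_force(self, rng):
        g = np.stack(np.meshgrid(*[np.arange(5)] * 2, [0.0]), -1).reshape(-1, 3) * 0.1
        pts = np.vstack([g, [[10.0, 10.0, 0.0]]])
        out = statistical_outlier_removal(PointCloud(pts), k=8, alpha=1.0)
        removed = {i for i in range(len(pts))
                   if not any(np.array_equal(pts[i], q) for q in out.points)}
        assert removed == brute_sor_removed(pts, 8, 1.0)
        assert len(pts) - 1 in removed

    def test_random_cloud_matches_brute_force(self, rng):
        pts = np.vstack([rng.normal(0, 0.05, (200, 3)), rng.uniform(1, 2, (12, 3))])
        out = statistical_outlier_removal(PointCloud(pts), k=10, alpha=1.5)
        kept = {tuple(p) for p in out.points}
        expected_removed = brute_sor_removed(pts, 10, 1.5)
        got_removed = {i for i in range(len(pts)) if tuple(pts[i]) not in kept}
        assert got_removed == expected_removed

    def test_duplicate_points_zero_variance_removes_nothing(self):
        pts = np.tile([[1.0, 2.0, 3.0]], (30, 1))
        out = statistical_outlier_removal(PointCloud(pts), k=5, alpha=2.0)
        assert len(out) == 30

    def test_never_removes_global_minimum_mu(self, rng):
        pts = rng.normal(size=(150, 3))
        mu = sor_mean_knn_distance(pts, 10)
        keeper = pts[np.argmin(mu)]
        out = statistical_outlier_removal(PointCloud(pts), k=10, alpha=0.01)
        assert any(np.array_equal(keeper, p) for p in out.points)

    def test_output_is_subset_preserving_order(self, rng):
        pts = rng.normal(size=(100, 3))
        out = statistical_outlier_removal(PointCloud(pts), k=10, alpha=1.0)
        kept_idx = [np.flatnonzero((pts == p).all(1))[0] for p in out.points]
        assert kept_idx == sorted(kept_idx)

    def test_k_exceeding_cloud_raises(self):
        with pytest.raises(ValueError, match="k exceeds"):
            statistical_outlier_removal(PointCloud(np.zeros((5, 3))), k=5, alpha=1.0)

    def test_literal_per_point_rule_flags_spread_points(self, rng):
        # the per-point variant compares each neighbour distance with the
        # point's own mu + alpha*sigma; with tight alpha it fires broadly
        pts = rng.normal(size=(100, 3))
        out = statistical_outlier_removal(PointCloud(pts), k=10, alpha=0.5, literal=True)
        assert len(out) < 100


def test_filter_params_validation():
    with pytest.raises(ValueError):
        FilterParams(dbscan_radius=-1)
    with pytest.raises(ValueError):
        FilterParams(sor_alpha=0)
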