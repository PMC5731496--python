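import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage

from conftop import (
    CalphaStructure,
    ClusterLevel,
    FilteredGraph,
    LandmarkSet,
    build_hierarchy,
    cluster_report,
    clusters_at_level,
    determine_cluster_count,
    determine_landmark_count,
    gaussian_blobs,
    lazy_witness_graph,
    maxmin_landmarks,
    prune_outliers,
)
from conftop.exceptions import ConsistencyError, EmptyResultError


def graph_with_merge_scales(deaths):
    """Path graph whose union-find merge scales are exactly ``deaths``."""
    n = len(deaths) + 1
    edges = np.array([[i, i + 1] for i in range(n - 1)])
    return FilteredGraph(vertices=np.arange(n), edges=edges, weights=np.array(deaths))


def dummy_landmarks(n):
    return LandmarkSet(indices=np.arange(n), coverage_radius=0.0)


class TestDetermineLandmarkCount:
    def test_micro_cluster_fixture_stops_early(self):
        # 10 point-like micro-clusters far apart: R collapses to 0 as soon as
        # every micro-cluster holds a landmark, so the 5% rule stops early
        rng = np.random.default_rng(0)
        centers = 50.0 * rng.standard_normal((10, 2))
        points = np.repeat(centers, 8, axis=0)
        n = determine_landmark_count(points, seed=0)
        assert n <= 30

    def test_identical_points_return_first_defined_count(self):
        pts = np.zeros((50, 2))
        # R = 0 everywhere: the difference test first applies at count 20
        assert determine_landmark_count(pts, seed=0) == 20

    def test_deterministic_under_seed(self, rng):
        pts = rng.standard_normal((80, 2))
        assert determine_landmark_count(pts, seed=5) == determine_landmark_count(pts, seed=5)

    def test_tiny_cloud_returns_size_with_warning(self, rng):
        pts = rng.standard_normal((6, 2))
        with pytest.warns(UserWarning):
            assert determine_landmark_count(pts, seed=0) == 6

    def test_capped_at_cloud_size(self, rng):
        pts = rng.standard_normal((15, 2))
        assert determine_landmark_count(pts, seed=1) <= 15


class TestDetermineClusterCount:
    def test_two_dominant_merges_give_three_clusters(self):
        deaths = [5.0, 4.9, 0.3, 0.28, 0.27, 0.2, 0.15]
        g = graph_with_merge_scales(deaths)
        n = len(deaths) + 1
        assert determine_cluster_count(None, dummy_landmarks(n), graph=g) == 3

    def test_no_gap_means_one_cluster(self):
        deaths = [0.50, 0.46, 0.44, 0.41]
        g = graph_with_merge_scales(deaths)
        assert determine_cluster_count(None, dummy_landmarks(5), graph=g) == 1

    def test_single_landmark_returns_one(self, rng):
        pts = rng.standard_normal((5, 2))
        assert determine_cluster_count(pts, dummy_landmarks(1)) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_three_blob_recovery(self, seed):
        cloud = gaussian_blobs(3, 50, separation=1.0, sigma=0.05, seed=seed)
        n = determine_landmark_count(cloud.points, seed=seed)
        landmarks = maxmin_landmarks(cloud.points, n, seed=seed)
        assert determine_cluster_count(cloud.points, landmarks) == 3

    def test_max_levels_limits_the_scan(self):
        # a deep gap beyond max_levels is ignored
        deaths = [10.0] + [5.0 - 0.01 * i for i in range(25)] + [0.1]
        g = graph_with_merge_scales(deaths)
        count = determine_cluster_count(None, dummy_landmarks(len(deaths) + 1),
                                        max_levels=5, graph=g)
        assert count == 2


class TestClustersAtLevel:
    def test_level_one_is_single_block(self, rng):
        pts = rng.standard_normal((20, 2))
        landmarks = maxmin_landmarks(pts, 10, seed=0)
        level = clusters_at_level(pts, landmarks, 1)
        assert level.n_blocks == 1
        assert len(level.partition[0]) == 10

    def test_level_l_is_all_singletons(self, rng):
        pts = rng.standard_normal((20, 2))
        landmarks = maxmin_landmarks(pts, 10, seed=0)
        level = clusters_at_level(pts, landmarks, 10)
        assert level.n_blocks == 10
        assert all(len(b) == 1 for b in level.partition)

    def test_three_blob_partition_matches_labels(self):
        cloud = gaussian_blobs(3, 30, separation=1.0, sigma=0.05, seed=1)
        landmarks = maxmin_landmarks(cloud.points, 30, seed=1)
        level = clusters_at_level(cloud.points, landmarks, 3)
        assert level.n_blocks == 3
        for block in level.partition:
            assert len(set(cloud.labels[block])) == 1

    def test_nesting_across_consecutive_levels(self, rng):
        pts = rng.standard_normal((30, 2))
        landmarks = maxmin_landmarks(pts, 12, seed=2)
        graph = lazy_witness_graph(pts, landmarks, nu=0)
        levels = [clusters_at_level(pts, landmarks, i, graph=graph) for i in range(1, 6)]
        for coarse, fine in zip(levels, levels[1:]):
            for block in fine.partition:
                supersets = [b for b in coarse.partition if set(block) <= set(b)]
                assert len(supersets) == 1


class TestPruneOutliers:
    def _level(self, blocks):
        return ClusterLevel(level=len(blocks), partition=[np.array(b) for b in blocks], scale=1.0)

    def test_no_small_blocks_is_identity(self):
        level = self._level([[0, 1, 2], [3, 4]])
        retained, pruned = prune_outliers(level, min_size=2)
        assert retained.tolist() == [0, 1, 2, 3, 4]
        assert pruned.n_blocks == 2

    def test_singleton_dropped(self):
        level = self._level([[0, 1, 2], [3, 4], [99]])
        retained, pruned = prune_outliers(level, min_size=2)
        assert 99 not in retained
        assert pruned.n_blocks == 2

    def test_min_size_one_is_always_identity(self):
        level = self._level([[0], [1], [2, 3]])
        retained, pruned = prune_outliers(level, min_size=1)
        assert pruned.n_blocks == 3

    def test_everything_pruned_raises(self):
        level = self._level([[0], [1]])
        with pytest.raises(EmptyResultError):
            prune_outliers(level, min_size=5)


class TestBuildHierarchy:
    def test_root_split_into_two_children(self):
        levels = [
            ClusterLevel(1, [np.arange(6)], 5.0),
            ClusterLevel(2, [np.arange(3), np.arange(3, 6)], 1.0),
        ]
        dendro = build_hierarchy(levels)
        root = [n for n in dendro.nodes if n.parent is None]
        assert len(root) == 1
        assert len(dendro.children(root[0].id)) == 2

    def test_single_level_gives_single_root(self):
        dendro = build_hierarchy([ClusterLevel(1, [np.arange(4)], 1.0)])
        assert len(dendro.nodes) == 1
        assert dendro.is_laminar()

    def test_violated_nesting_raises(self):
        levels = [
            ClusterLevel(2, [np.array([0, 1]), np.array([2, 3])], 5.0),
            ClusterLevel(2, [np.array([0, 2]), np.array([1, 3])], 1.0),
        ]
        with pytest.raises(ConsistencyError):
            build_hierarchy(levels)

    def test_matches_single_linkage_tree_on_fixture(self, rng):
        """With full landmarks and nu=0 the filtration is single linkage, so
        every level partition must match scipy fcluster at that level."""
        pts = rng.standard_normal((15, 2))
        landmarks = LandmarkSet(indices=np.arange(15), coverage_radius=0.0)
        graph = lazy_witness_graph(pts, landmarks, nu=0)
        Z = linkage(pts, method="single")
        levels = []
        for i in range(1, 6):
            level = clusters_at_level(pts, landmarks, i, graph=graph)
            levels.append(level)
            ref = fcluster(Z, t=i, criterion="maxclust")
            ours = np.empty(15, dtype=int)
            for c, block in enumerate(level.partition):
                ours[block] = c
            # same partition up to labels
            pairs_ref = {(a, b) for a in range(15) for b in range(15) if ref[a] == ref[b]}
            pairs_ours = {(a, b) for a in range(15) for b in range(15) if ours[a] == ours[b]}
            assert pairs_ref == pairs_ours
        assert build_hierarchy(levels).is_laminar()


class TestClusterReport:
    # scaled copies of a centered cross: optimal superposition is the identity,
    # so the RMSD of the scale-c copy to the base is exactly 2*(c-1)
    BASE = np.array([[2.0, 0, 0], [0, 2.0, 0], [-2.0, 0, 0], [0, -2.0, 0]])

    def _structures(self, scales):
        return [
            CalphaStructure(f"s{c}", np.arange(1, 5), c * self.BASE) for c in scales
        ]

    def test_copies_of_endpoint_have_zero_mean_and_sd(self):
        structures = self._structures([1.0, 1.0, 1.0, 2.0])
        report = cluster_report(
            [np.array([0, 1, 2])], structures, structures[0], structures[3],
            reduced_points=np.zeros((4, 2)),
        )
        row = report.table.iloc[0]
        assert row["mean_rmsd_a"] == pytest.approx(0.0, abs=1e-9)
        assert row["sd_rmsd_a"] == pytest.approx(0.0, abs=1e-9)

    def test_single_member_cluster_has_zero_sd(self):
        structures = self._structures([1.0, 3.0])
        report = cluster_report(
            [np.array([1])], structures, structures[0], structures[0],
            reduced_points=np.zeros((2, 2)),
        )
        assert report.table.iloc[0]["sd_rmsd_a"] == pytest.approx(0.0)

    def test_population_sd_hand_computed(self):
        # members at scales 3 and 4 sit at RMSD 4 and 6: mean 5, population sd 1
        structures = self._structures([1.0, 3.0, 4.0])
        report = cluster_report(
            [np.array([1, 2])], structures, structures[0], structures[0],
            reduced_points=np.zeros((3, 2)),
        )
        row = report.table.iloc[0]
        assert row["mean_rmsd_a"] == pytest.approx(5.0, abs=1e-9)
        assert row["sd_rmsd_a"] == pytest.approx(1.0, abs=1e-9)

    def test_ordering_invariant_under_relabeling(self):
        structures = self._structures([1.0, 2.0, 2.05, 4.0, 4.05])
        a, b = structures[0], structures[-1]
        reduced = np.arange(10).reshape(5, 2).astype(float)
        blocks = [np.array([1, 2]), np.array([3, 4])]
        r1 = cluster_report(blocks, structures, a, b, reduced)
        r2 = cluster_report(blocks[::-1], structures, a, b, reduced)
        assert r1.table["mean_rmsd_a"].tolist() == r2.table["mean_rmsd_a"].tolist()
        assert r1.table["cluster"].tolist() == [1, 2]

    def test_representative_is_reduced_space_medoid(self):
        structures = self._structures([1.0, 1.5, 1.6, 2.0])
        reduced = np.array([[0.0, 0], [1.0, 0], [1.2, 0], [5.0, 0]])
        report = cluster_report(
            [np.array([0, 1, 2, 3])], structures, structures[0], structures[0], reduced
        )
        # centre is (1.8, 0); nearest member is index 2 at 1.2
        assert report.table.iloc[0]["representative"] == 2
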