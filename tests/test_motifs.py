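import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import davies_bouldin_score

from meaburst import (ActivationPattern, circular_angle_difference,
                      circular_mean, cluster, cluster_major_directions,
                      davies_bouldin, planar_wave_latencies, prepare_features,
                      select_k)


def _accuracy(labels, truth):
    """Best agreement over label permutations (2 clusters)."""
    labels, truth = np.asarray(labels), np.asarray(truth)
    a = np.mean(labels == truth)
    swapped = np.where(labels == 1, 2, 1)
    return max(a, np.mean(swapped == truth))


class TestDaviesBouldin:
    def test_hand_computable_fixture(self):
        """A={(0,0),(0,1)}, B={(10,0),(10,1)}: S=0.5 each, M=10, DB=0.1."""
        X = np.array([[0, 0], [0, 1], [10, 0], [10, 1]], dtype=float)
        lab = np.array([1, 1, 2, 2])
        assert davies_bouldin(X, lab) == pytest.approx(0.1)

    def test_singleton_clusters_give_zero(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0]])
        assert davies_bouldin(X, np.array([1, 2])) == 0.0

    def test_shrinking_spread_decreases_db(self, rng):
        c = np.r_[np.zeros((50, 2)), np.full((50, 2), 8.0)]
        noise = rng.normal(size=(100, 2))
        lab = np.r_[np.ones(50), np.full(50, 2)]
        dbs = [davies_bouldin(c + s * noise, lab) for s in (1.0, 0.5, 0.2)]
        assert dbs[0] > dbs[1] > dbs[2]

    def test_matches_sklearn_reference(self, rng):
        """Cross-check against the independent sklearn implementation."""
        X = rng.normal(size=(100, 3))
        lab = rng.integers(1, 5, size=100)
        assert davies_bouldin(X, lab) == pytest.approx(
            davies_bouldin_score(X, lab))

    def test_coincident_centroids_rejected(self):
        X = np.array([[0.0, 1.0], [0.0, -1.0], [0.0, 2.0], [0.0, -2.0]])
        lab = np.array([1, 1, 2, 2])
        with pytest.raises(ValueError, match="coincident"):
            davies_bouldin(X, lab)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            davies_bouldin(np.zeros((5, 2)), np.ones(5))

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 1000))
    def test_label_permutation_invariance(self, seed):
        r = np.random.default_rng(seed)
        X = r.normal(size=(30, 2))
        lab = r.integers(1, 4, size=30)
        if np.unique(lab).size < 2:
            return
        perm = r.permutation([1, 2, 3])
        try:
            a = davies_bouldin(X, lab)
        except ValueError:
            return
        assert davies_bouldin(X, perm[lab - 1]) == pytest.approx(a)


class TestCluster:
    def test_two_point_masses_split_perfectly(self):
        X = np.r_[np.zeros((50, 2)), np.full((50, 2), 3.0)]
        lab = cluster(X, "kmeans", k=2, seed=0)
        assert np.unique(lab[:50]).size == 1
        assert np.unique(lab[50:]).size == 1
        assert lab[0] != lab[-1]

    def test_k_beyond_distinct_rows_rejected(self):
        X = np.r_[np.zeros((5, 2)), np.ones((5, 2))]
        with pytest.raises(ValueError, match="distinct"):
            cluster(X, "kmeans", k=3)

    @pytest.mark.parametrize("method", ["kmeans", "em"])
    def test_six_planted_blobs_recovered(self, method, rng):
        centers = rng.normal(scale=20.0, size=(6, 3))
        X = np.concatenate([c + rng.normal(size=(40, 3)) for c in centers])
        truth = np.repeat(np.arange(6), 40)
        lab = cluster(X, method, k=6, seed=1)
        # agreement up to permutation: every planted blob maps to one label
        hits = 0
        for b in range(6):
            vals, cnts = np.unique(lab[truth == b], return_counts=True)
            hits += cnts.max()
        assert hits / X.shape[0] >= 0.99

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(60, 2))
        a = cluster(X, "em", k=3, seed=5)
        b = cluster(X, "em", k=3, seed=5)
        assert np.array_equal(a, b)


class TestSelectK:
    def test_three_blobs(self, rng):
        X = np.concatenate([c + 0.3 * rng.normal(size=(40, 2))
                            for c in ([0, 0], [6, 0], [0, 6])])
        k_opt, curve = select_k(X, "kmeans", k_range=range(2, 8), seed=0)
        assert k_opt == 3

    def test_two_blobs_robust_db(self, rng):
        X = np.concatenate([c + 0.3 * rng.normal(size=(50, 2))
                            for c in ([0, 0], [7, 0])])
        k_opt, curve = select_k(X, "kmeans", k_range=range(2, 8), seed=0)
        assert k_opt == 2
        assert curve[2] < 1.0

    def test_single_blob_lacks_robust_two_cluster_structure(self, rng):
        """An isotropic blob split in two scores far worse than genuinely
        bimodal data at k=2 — the no-motif flag for regular superbursts."""
        null = rng.normal(size=(100, 2))
        two = np.concatenate([c + 0.3 * rng.normal(size=(50, 2))
                              for c in ([0, 0], [7, 0])])
        _, curve_null = select_k(null, "kmeans", k_range=range(2, 6), seed=0)
        _, curve_two = select_k(two, "kmeans", k_range=range(2, 6), seed=0)
        assert curve_null[2] > 2 * curve_two[2]


class TestPrepareFeatures:
    def _two_motif_patterns(self, layout, n=30, rng=None):
        rng = rng or np.random.default_rng(0)
        aps = []
        for i in range(n):
            ang = 20.0 if i % 2 == 0 else 115.0
            lat = planar_wave_latencies(layout, ang, 100.0, 0.001, 0.05, rng)
            aps.append(ActivationPattern(i, lat))
        return aps

    def test_rank_two_data_fully_explained(self, layout):
        """Patterns lying in a 2-D latency subspace: 2 PCs explain ~100%."""
        rng = np.random.default_rng(1)
        b1 = rng.normal(size=59)
        b2 = rng.normal(size=59)
        aps = [ActivationPattern(i, a * b1 + b * b2)
               for i, (a, b) in enumerate(rng.normal(size=(20, 2)))]
        fs = prepare_features(aps, n_pcs=2)
        assert fs.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_duplicates_get_identical_scores(self, layout):
        aps = self._two_motif_patterns(layout, n=10)
        fs = prepare_features(aps + aps, n_pcs=2)
        assert np.allclose(fs.scores[:10], fs.scores[10:])

    def test_planted_motifs_linearly_separable_on_pc1(self, layout):
        aps = self._two_motif_patterns(layout, n=40)
        fs = prepare_features(aps, n_pcs=2)
        pc1_a = fs.scores[::2, 0]
        pc1_b = fs.scores[1::2, 0]
        assert max(pc1_a.min(), pc1_b.min()) > min(pc1_a.max(), pc1_b.max()) \
            or pc1_a.max() < pc1_b.min() or pc1_b.max() < pc1_a.min()

    def test_all_missing_electrode_dropped(self, layout):
        aps = self._two_motif_patterns(layout, n=12)
        for ap in aps:
            ap.latencies[7] = np.nan
        fs = prepare_features(aps, n_pcs=2)
        assert 7 not in fs.electrodes_kept
        assert fs.scores.shape == (12, 2)


class TestAngleClustering:
    def test_two_tight_clouds(self, rng):
        angles = np.r_[rng.normal(30.0, 3.0, 100), rng.normal(300.0, 3.0, 100)]
        model = cluster_major_directions(angles, k=2, seed=0)
        means = np.sort(model.motif_angles)
        assert circular_angle_difference(means[0], 30.0) < 2.0
        assert circular_angle_difference(means[1], 300.0) < 2.0
        assert model.db < 1.0

    def test_antipodal_clouds(self, rng):
        angles = np.r_[rng.normal(0.0, 2.0, 50) % 360, rng.normal(180.0, 2.0, 50)]
        model = cluster_major_directions(angles, k=2, seed=0)
        assert model.db < 0.2

    def test_wraparound_cloud_not_split_at_zero(self, rng):
        """A cloud spanning 350°–10° is one tight cluster on the circle:
        its two km-subclusters stay adjacent, and each circular mean lies
        inside the cloud rather than at the 180° linear average."""
        angles = rng.uniform(-10.0, 10.0, 200) % 360.0
        model = cluster_major_directions(angles, k=2, seed=0)
        for m in model.motif_angles:
            assert circular_angle_difference(m, 0.0) < 10.0

    def test_identical_angles_rejected(self):
        with pytest.raises(ValueError):
            cluster_major_directions(np.full(10, 45.0), k=2)


class TestCircularHelpers:
    @pytest.mark.parametrize("a,b,expected", [
        (29.0, 302.0, 87.0),
        (0.0, 0.0, 0.0),
        (10.0, 350.0, 20.0),
        (90.0, 270.0, 180.0),
    ])
    def test_angle_difference(self, a, b, expected):
        assert circular_angle_difference(a, b) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-720, 720), st.floats(-720, 720), st.floats(-720, 720))
    def test_angle_difference_properties(self, a, b, shift):
        d = circular_angle_difference(a, b)
        assert 0.0 <= d <= 180.0
        assert circular_angle_difference(b, a) == pytest.approx(d)
        assert circular_angle_difference(a + shift, b + shift) == \
            pytest.approx(d, abs=1e-6)

    def test_circular_mean_wraparound(self):
        assert circular_angle_difference(
            circular_mean(np.array([350.0, 10.0])), 0.0) < 1e-9
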