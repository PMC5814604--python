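"""Lloyd k-means against a brute-force partition oracle, elbow rule, naming."""

from itertools import product

import numpy as np
import pytest

from acticlust import MINUTES_PER_DAY, elbow_scan, lloyd_kmeans, name_clusters
from acticlust.clustering import ElbowScan
from acticlust.smoothing import SmoothedCurves


def brute_force_optimum(x: np.ndarray, k: int) -> float:
    """Exhaustive minimum WSS over all assignments of n points to k clusters."""
    n = len(x)
    best = np.inf
    for assign in product(range(k), repeat=n):
        assign = np.array(assign)
        if len(np.unique(assign)) < k:
            continue
        wss = 0.0
        for c in range(k):
            pts = x[assign == c]
            wss += ((pts - pts.mean(axis=0)) ** 2).sum()
        best = min(best, wss)
    return best


class TestLloyd:
    def test_perfectly_separated_pairs(self):
        x = np.array([[0.0], [0.0], [10.0], [10.0]])
        res = lloyd_kmeans(x, 2, seed=0)
        assert res.wss == pytest.approx(0.0)
        assert res.variance_explained == pytest.approx(1.0)
        assert sorted(res.centroids.ravel()) == [0.0, 10.0]

    def test_k1_closed_form(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(20, 3))
        res = lloyd_kmeans(x, 1, seed=0)
        np.testing.assert_allclose(res.centroids[0], x.mean(axis=0))
        assert res.wss == pytest.approx(res.tss)
        assert res.variance_explained == pytest.approx(0.0)

    @pytest.mark.parametrize("bad_k", [0, -1, 100])
    def test_invalid_k(self, bad_k):
        x = np.zeros((5, 2))
        with pytest.raises(ValueError):
            lloyd_kmeans(x, bad_k, seed=0)

    def test_missing_values_rejected(self):
        x = np.zeros((5, 2))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            lloyd_kmeans(x, 2, seed=0)

    def test_centroids_are_cluster_means(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(40, 5))
        res = lloyd_kmeans(x, 3, seed=1)
        for c in range(3):
            np.testing.assert_allclose(
                res.centroids[c], x[res.labels == c].mean(axis=0), atol=1e-9
            )
        assert np.all(res.cluster_sizes() > 0)

    def test_best_of_restarts_bookkeeping(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(30, 2))
        res = lloyd_kmeans(x, 3, restarts=25, seed=2)
        assert res.wss == pytest.approx(res.per_restart_wss.min())
        assert res.best_restart == int(np.argmin(res.per_restart_wss))
        assert res.per_restart_wss.shape == (25,)

    def test_wss_monotone_within_restart(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(100, 4))
        res = lloyd_kmeans(x, 4, seed=3)
        hist = np.array(res.wss_history)
        assert np.all(np.diff(hist) <= 1e-9 * res.tss)

    def test_matches_brute_force_small(self):
        """25 restarts reach the exhaustive-partition optimum on small data."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.uniform(size=(7, 2))
            res = lloyd_kmeans(x, 2, restarts=25, seed=seed)
            if res.wss <= brute_force_optimum(x, 2) + 1e-9:
                hits += 1
        assert hits >= 19

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(50, 3))
        r1 = lloyd_kmeans(x, 3, seed=42)
        r2 = lloyd_kmeans(x, 3, seed=42)
        np.testing.assert_array_equal(r1.labels, r2.labels)
        assert r1.wss == r2.wss

    def test_label_permutation_leaves_wss_unchanged(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(30, 2))
        res = lloyd_kmeans(x, 3, seed=4)
        perm = np.array([2, 0, 1])
        wss_perm = sum(
            ((x[perm[res.labels] == c] - res.centroids[perm == c][0]) ** 2).sum()
            for c in range(3)
        )
        assert wss_perm == pytest.approx(res.wss)

    def test_agrees_with_reference_kmeans(self):
        """Independent cross-check: best WSS within a hair of scikit-learn's."""
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(10)
        x = np.concatenate([rng.normal(c, 0.3, size=(30, 4)) for c in (0, 3, 6)])
        ours = lloyd_kmeans(x, 3, restarts=25, seed=5)
        ref = KMeans(3, n_init=10, random_state=0).fit(x)
        assert ours.wss == pytest.approx(ref.inertia_, rel=1e-6)

    def test_kmeanspp_init_available(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(30, 2))
        res = lloyd_kmeans(x, 3, seed=6, init="k-means++")
        assert res.k == 3 and np.all(res.cluster_sizes() > 0)


class TestElbow:
    def test_forced_scan_rule(self):
        from acticlust.clustering import choose_elbow_k

        # 100->20 is an 80% cut, 20->19 only 5% -> stop at k=2
        assert choose_elbow_k([100.0, 20.0, 19.0, 18.0], 0.10) == 2
        # geometric halving: every reduction is 50% >= threshold -> k_max
        assert choose_elbow_k([64.0, 32.0, 16.0, 8.0], 0.10) == 4
        # WSS hits zero: adding clusters past it cannot help
        assert choose_elbow_k([10.0, 0.0, 0.0], 0.10) == 2

    def test_rule_on_synthetic_wss(self):
        # three well-separated blobs in 10-D: big cuts until k=3, then
        # splitting isotropic noise buys only ~6% per extra cluster
        rng = np.random.default_rng(13)
        x = np.concatenate([rng.normal(c, 0.5, size=(20, 10)) for c in (0, 3, 6)])
        scan = elbow_scan(x, k_max=5, restarts=25, seed=7)
        assert scan.chosen_k == 3
        assert np.all(np.diff(scan.wss_by_k) <= 1e-9)  # non-increasing in k

    def test_no_plateau_chooses_kmax(self):
        # unstructured low-dim data: every extra cluster keeps cutting WSS by
        # well over 5%, so the scan runs out at k_max
        rng = np.random.default_rng(14)
        x = rng.normal(size=(40, 2))
        scan = elbow_scan(x, k_max=3, restarts=10, seed=8, threshold=0.05)
        assert scan.chosen_k == 3

    def test_kmax_validation(self):
        with pytest.raises(ValueError):
            elbow_scan(np.zeros((5, 2)), k_max=1)


class TestNaming:
    def _curves(self, curves_dict):
        return SmoothedCurves(
            minute_grid=np.arange(MINUTES_PER_DAY),
            curves=curves_dict,
            raw_means=curves_dict,
            span=0.1,
        )

    def _result(self, k):
        # minimal stand-in result; naming only consults the curves
        from acticlust.clustering import ClusteringResult

        return ClusteringResult(
            labels=np.arange(k), centroids=np.zeros((k, 1)), wss=0.0, tss=1.0,
            restarts=1, seed=0, per_restart_wss=np.zeros(1), best_restart=0, n_iter=1,
        )

    @staticmethod
    def bump(center, height, width=60):
        m = np.arange(MINUTES_PER_DAY)
        return 1.0 + height * np.exp(-0.5 * ((m - center) / width) ** 2)

    def test_raw_morning_afternoon_unengaged(self):
        curves = self._curves(
            {
                0: self.bump(540, 2.0),            # peaks 09:00
                1: self.bump(900, 2.0),            # peaks 15:00
                2: np.full(MINUTES_PER_DAY, 1.0),  # flat and lowest
            }
        )
        names = name_clusters(self._result(3), curves, "raw")
        assert names == {0: "morning", 1: "afternoon", 2: "unengaged"}

    def test_normalized_peak_names(self):
        two_peaks = self.bump(450, 1.0, 40) + self.bump(1050, 0.9, 40) - 1.0
        curves = self._curves(
            {
                0: two_peaks,                # 07:30 and 17:30
                1: self.bump(720, 1.0, 40),  # noon
                2: self.bump(1000, 1.0, 40), # evening
            }
        )
        names = name_clusters(self._result(3), curves, "normalized_mvpa")
        assert names[0] == "morning_and_evening_peak"
        assert names[1] == "noon_peak"
        assert names[2] == "evening_peak"

    def test_duplicate_names_get_suffix(self):
        curves = self._curves({0: self.bump(500, 2.0), 1: self.bump(520, 2.0),
                               2: np.full(MINUTES_PER_DAY, 1.0)})
        names = name_clusters(self._result(3), curves, "raw")
        assert names[0] == "morning" and names[1] == "morning_2"
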