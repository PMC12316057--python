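"""K-means engine: closed forms, enumeration oracle, determinism, harmonization."""

import dataclasses
import itertools

import numpy as np
import pytest

from afseg.gabor import FeatureStack
from afseg.kmeans import (
    KMeansConfig,
    KMeansResult,
    harmonize_volume,
    inertia,
    kmeans,
    segment_slice,
)


def brute_force_two_means(points):
    """Global optimum of 2-means by enumerating all bipartitions."""
    n = len(points)
    best = np.inf
    for bits in range(1, 2 ** (n - 1)):
        mask = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        if not mask.any() or mask.all():
            continue
        sse = 0.0
        for part in (points[mask], points[~mask]):
            sse += ((part - part.mean(axis=0)) ** 2).sum()
        best = min(best, sse)
    return best


class TestInertia:
    def test_points_on_centroids(self):
        pts = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert inertia(pts, pts.copy(), np.array([0, 1])) == 0.0

    def test_single_distance(self):
        pts = np.array([[3.0, 4.0]])
        cents = np.array([[0.0, 0.0]])
        assert inertia(pts, cents, np.array([0])) == pytest.approx(25.0)

    def test_hand_summed_1d(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        cents = np.array([[1.0]])
        assert inertia(pts, cents, np.zeros(3, dtype=int)) == pytest.approx(2.0)

    def test_out_of_range_assignment(self):
        pts = np.zeros((2, 1))
        with pytest.raises(ValueError):
            inertia(pts, np.zeros((1, 1)), np.array([0, 3]))


class TestKMeansClosedForms:
    def test_k1_centroid_is_mean(self, rng):
        pts = rng.normal(size=(40, 3))
        res = kmeans(pts, KMeansConfig(K=1, seed=0))
        np.testing.assert_allclose(res.centroids[0], pts.mean(axis=0))
        expect = ((pts - pts.mean(axis=0)) ** 2).sum()
        assert res.objective == pytest.approx(expect)

    def test_k_equals_n_zero_objective(self, rng):
        pts = rng.normal(size=(6, 2)) * 10
        res = kmeans(pts, KMeansConfig(K=6, n_restarts=10, seed=0))
        assert res.objective == pytest.approx(0.0, abs=1e-18)

    def test_square_corner_pairs(self):
        # well-separated square: the optimal 2-partition pairs the close
        # corners; its objective equals the enumerated minimum
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        res = kmeans(pts, KMeansConfig(K=2, n_restarts=5, seed=1))
        assert res.objective == pytest.approx(brute_force_two_means(pts))
        assert res.objective == pytest.approx(1.0)  # two pairs, 0.5^2 * 2 each


class TestKMeansOracle:
    def test_matches_enumeration_on_random_instances(self):
        """Over >= 50 random instances the Lloyd+restarts engine attains the
        enumerated global optimum in >= 95% and never beats it."""
        rng = np.random.default_rng(2024)
        hits = 0
        n_instances = 60
        for _ in range(n_instances):
            n = int(rng.integers(4, 11))
            f = int(rng.integers(1, 3))
            pts = rng.normal(size=(n, f)) * rng.uniform(0.5, 3.0)
            res = kmeans(pts, KMeansConfig(K=2, n_restarts=10, seed=int(rng.integers(2**31))))
            best = brute_force_two_means(pts)
            assert res.objective >= best - 1e-9  # never better than global
            if res.objective <= best * (1 + 1e-9) + 1e-12:
                hits += 1
        assert hits / n_instances >= 0.95

    def test_cross_check_against_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.cluster")
        pts = np.vstack(
            [rng.normal(loc=c, scale=0.3, size=(50, 4)) for c in (0.0, 3.0, 6.0)]
        )
        ours = kmeans(pts, KMeansConfig(K=3, n_restarts=10, seed=0))
        theirs = sklearn.KMeans(n_clusters=3, n_init=10, random_state=0).fit(pts)
        assert ours.objective == pytest.approx(theirs.inertia_, rel=1e-6)


class TestKMeansBehaviour:
    def test_objective_history_non_increasing(self, rng):
        pts = rng.normal(size=(300, 5))
        res = kmeans(pts, KMeansConfig(K=4, n_restarts=1, seed=3))
        hist = res.objective_history
        assert len(hist) >= 1
        assert all(a >= b - 1e-9 for a, b in zip(hist, hist[1:]))

    def test_deterministic_given_seed(self, rng):
        pts = rng.normal(size=(100, 3))
        a = kmeans(pts, KMeansConfig(K=3, seed=9))
        b = kmeans(pts, KMeansConfig(K=3, seed=9))
        np.testing.assert_array_equal(a.assignments, b.assignments)
        np.testing.assert_array_equal(a.centroids, b.centroids)
        assert a.objective == b.objective

    def test_objective_consistent_with_inertia(self, rng):
        pts = rng.normal(size=(200, 4))
        res = kmeans(pts, KMeansConfig(K=3, seed=1))
        assert res.objective == pytest.approx(
            inertia(pts, res.centroids, res.assignments), rel=1e-9
        )
        assert res.objective == pytest.approx(min(res.restart_objectives), rel=1e-12)

    def test_tie_goes_to_lowest_centroid_index(self):
        # one point exactly between two centroids: with K=N init at the
        # points themselves, the midpoint joins the lower-index cluster
        pts = np.array([[0.0], [1.0], [2.0], [3.0]])
        res = kmeans(pts, KMeansConfig(K=4, n_restarts=20, seed=0))
        d2 = (pts[:, None, :] - res.centroids[None]) ** 2
        assign = d2.sum(-1).argmin(1)
        np.testing.assert_array_equal(res.assignments, assign)

    def test_random_points_init_supported(self, rng):
        pts = rng.normal(size=(50, 2))
        res = kmeans(pts, KMeansConfig(K=3, init="random-points", seed=4))
        assert isinstance(res, KMeansResult)
        assert set(np.unique(res.assignments)) <= {0, 1, 2}

    def test_invalid_inputs(self, rng):
        pts = rng.normal(size=(3, 2))
        with pytest.raises(ValueError):
            kmeans(pts, KMeansConfig(K=5, seed=0))  # N < K
        bad = pts.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            kmeans(bad, KMeansConfig(K=2, seed=0))
        with pytest.raises(ValueError):
            kmeans(pts, KMeansConfig(K=2, init="bogus", seed=0))

    def test_subsample_predicts_all_points(self, rng):
        pts = np.vstack(
            [rng.normal(loc=c, scale=0.2, size=(300, 2)) for c in (0.0, 5.0)]
        )
        cfg = KMeansConfig(K=2, seed=0, subsample=100)
        res = kmeans(pts, cfg)
        assert len(res.assignments) == 600
        # the two blobs separate perfectly even when fit on a subset
        left = set(res.assignments[:300])
        right = set(res.assignments[300:])
        assert len(left) == len(right) == 1 and left != right


def _stack_from_planes(planes, names, spatial_indices=()):
    planes = np.stack(planes, axis=-1)
    f = planes.shape[-1]
    return FeatureStack(
        planes=planes,
        names=names,
        means=np.zeros(f),
        sds=np.ones(f),
        constant=np.zeros(f, dtype=bool),
        spatial_weight=1.0,
        spatial_indices=list(spatial_indices),
    )


class TestSegmentSlice:
    def test_half_bright_half_dark_split_exactly(self):
        img = np.zeros((8, 8))
        img[:, 4:] = 1.0
        feats = _stack_from_planes([img], ["intensity"])
        labels, _ = segment_slice(feats, KMeansConfig(K=2, seed=0))
        assert len(np.unique(labels[:, :4])) == 1
        assert len(np.unique(labels[:, 4:])) == 1
        assert labels[0, 0] != labels[0, 7]

    def test_k1_constant_map(self, rng):
        feats = _stack_from_planes([rng.uniform(size=(6, 6))], ["intensity"])
        labels, res = segment_slice(feats, KMeansConfig(K=1, seed=0))
        assert (labels == 0).all()
        assert res.n_iter >= 1


class TestHarmonizeVolume:
    def _result(self, labels, centroids):
        return KMeansResult(
            centroids=np.asarray(centroids, dtype=float),
            assignments=labels.ravel(),
            objective=0.0,
            n_iter=1,
            restart_objectives=[0.0],
        )

    def test_single_slice_passthrough(self):
        lm = np.array([[0, 1], [2, 0]])
        out = harmonize_volume([(lm, self._result(lm, [[0.0], [1.0], [2.0]]))])
        np.testing.assert_array_equal(out.data[0], lm)

    def test_known_permutation_inverted(self):
        lm0 = np.array([[0, 1], [2, 0]])
        cents0 = np.array([[0.0], [1.0], [2.0]])
        perm = np.array([2, 0, 1])  # slice-1 cluster i corresponds to perm[i]
        lm1 = np.empty_like(lm0)
        for old, new in enumerate(perm):
            lm1[lm0 == old] = new
        cents1 = np.empty_like(cents0)
        for old, new in enumerate(perm):
            cents1[new] = cents0[old]
        out = harmonize_volume(
            [
                (lm0, self._result(lm0, cents0)),
                (lm1, self._result(lm1, cents1)),
            ]
        )
        np.testing.assert_array_equal(out.data[1], lm0)

    def test_identical_slices_stay_identical(self):
        lm = np.array([[0, 1], [1, 0]])
        cents = np.array([[0.0, 0.0], [1.0, 1.0]])
        out = harmonize_volume([(lm, self._result(lm, cents))] * 3)
        for z in range(3):
            np.testing.assert_array_equal(out.data[z], lm)

    def test_appearance_indices_used_for_matching(self):
        # centroids differ wildly on the excluded (spatial) column but match
        # on the appearance column; matching must follow appearance only
        lm0 = np.array([[0, 1]])
        lm1 = np.array([[1, 0]])
        cents0 = np.array([[0.0, 100.0], [5.0, -100.0]])
        cents1 = np.array([[5.0, 100.0], [0.0, -100.0]])
        out = harmonize_volume(
            [(lm0, self._result(lm0, cents0)), (lm1, self._result(lm1, cents1))],
            appearance_indices=[0],
        )
        np.testing.assert_array_equal(out.data[1], lm0)

    def test_differing_k_rejected(self):
        lm = np.array([[0, 1]])
        a = self._result(lm, [[0.0], [1.0]])
        b = self._result(lm, [[0.0], [1.0], [2.0]])
        with pytest.raises(ValueError, match="cluster counts"):
            harmonize_volume([(lm, a), (lm, b)])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            harmonize_volume([])
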