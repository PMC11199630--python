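"""dCrawler phases and end-to-end clustering behaviour."""

import numpy as np
import pytest

from qdyefinder.colour_space import ColourVector, vector_normalize
from qdyefinder.dcrawler import UNASSIGNED, adjust, crawl, dcrawler, merge


def _unit_rows(raw):
    raw = np.asarray(raw, dtype=float)
    return raw / np.linalg.norm(raw, axis=1, keepdims=True)


def _blobs(rng, centers, n_per, spread):
    """Nonnegative unit-vector blobs around given hue centres."""
    pts, labels = [], []
    centers = _unit_rows(centers)
    for i, c in enumerate(centers):
        for _ in range(n_per):
            v = np.clip(c + rng.normal(0, spread, len(c)), 1e-6, None)
            pts.append(v / np.linalg.norm(v))
            labels.append(i)
    return np.array(pts), np.array(labels)


class TestCrawl:
    def test_single_point_seeds_single_cluster(self):
        v = np.array([[0.6, 0.8]])
        w = np.ones(1)
        a, c = crawl(v, w, np.full(1, UNASSIGNED), np.empty((0, 2)), 0.2)
        assert a.tolist() == [0]
        np.testing.assert_allclose(c[0], v[0])

    @pytest.mark.parametrize(
        "d, expected_clusters", [(0.1, 1), (0.5, 2)]
    )
    def test_pair_within_or_beyond_threshold(self, d, expected_clusters):
        # two unit vectors at exactly distance d
        theta = 2 * np.arcsin(d / 2)
        v = np.array([[1.0, 0.0], [np.cos(theta), np.sin(theta)]])
        w = np.ones(2)
        a, c = crawl(v, w, np.full(2, UNASSIGNED), np.empty((0, 2)), 0.2)
        assert len(c) == expected_clusters

    def test_centroid_updates_during_accretion(self):
        v = np.array([[1.0, 0.0], [0.9, 0.1]])
        v = _unit_rows(v)
        w = np.array([1.0, 3.0])
        a, c = crawl(v, w, np.full(2, UNASSIGNED), np.empty((0, 2)), 0.5)
        expected = (v[0] * 1 + v[1] * 3) / 4
        np.testing.assert_allclose(c[0], expected)


class TestAdjust:
    def test_fixed_point_is_unchanged(self, rng):
        v, labels = _blobs(rng, np.eye(3), 10, 0.01)
        w = np.ones(len(v))
        cents = np.stack([v[labels == i].mean(axis=0) for i in range(3)])
        a1, c1 = adjust(v, w, labels.copy(), cents)
        a2, c2 = adjust(v, w, a1, c1)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_allclose(c1, c2)

    def test_tie_goes_to_lower_cluster_id(self):
        # two anchor points fix the centroids; a zero-weight probe sits
        # exactly between them and must land in the lower cluster id
        v = np.array([[0.4, 0.6], [0.6, 0.4], [0.5, 0.5]])
        w = np.array([1.0, 1.0, 0.0])
        a, _ = adjust(v, w, np.array([0, 1, 1]), v[:2].copy())
        assert a[2] == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_nearest_centroid(self, seed):
        """Exhaustive oracle: converged assignment == nearest-centroid map."""
        rng = np.random.default_rng(seed)
        v, labels = _blobs(rng, rng.uniform(0.1, 1, (4, 5)), 15, 0.05)
        w = rng.uniform(0.5, 2.0, len(v))
        start = rng.integers(0, 4, len(v))
        cents = np.stack(
            [v[start == i].mean(axis=0) if (start == i).any() else rng.uniform(0, 1, 5)
             for i in range(4)]
        )
        a, c = adjust(v, w, start, cents)
        brute = np.array(
            [np.argmin([np.linalg.norm(p - cc) for cc in c]) for p in v]
        )
        np.testing.assert_array_equal(a, brute)


class TestMerge:
    def test_distant_centroids_untouched(self, rng):
        v, labels = _blobs(rng, np.eye(3), 8, 0.01)
        w = np.ones(len(v))
        cents = np.stack([v[labels == i].mean(axis=0) for i in range(3)])
        a, c = merge(v, w, labels.copy(), cents, 0.2, 0.2)
        assert len(c) == 3
        np.testing.assert_array_equal(np.sort(np.unique(a)), [0, 1, 2])

    def test_close_pair_fuses(self):
        v = _unit_rows([[1.0, 0.02], [1.0, 0.06]])
        w = np.ones(2)
        a, c = merge(v, w, np.array([0, 1]), v.copy(), 0.2, 0.2)
        assert len(c) == 1
        assert a.tolist() == [0, 0]

    def test_closest_first_agglomeration_matches_oracle(self):
        """Three collinear centroids, spacing 0.15, threshold 0.2.

        Closest-first oracle by hand: fuse (0, 0.15) -> centroid at 0.075;
        its distance to 0.30 is 0.225 > 0.2, so agglomeration stops at two
        clusters (a single pass merging every pair under 0.2 would instead
        have fused all three)."""
        base = np.array([[1.0, 0.0], [1.0, 0.15], [1.0, 0.30]])
        a = np.array([0, 1, 2])
        w = np.ones(3)
        got_a, got_c = merge(base, w, a, base.copy(), 0.2, np.inf)
        assert len(got_c) == 2
        np.testing.assert_allclose(got_c[0], [1.0, 0.075])
        np.testing.assert_allclose(got_c[1], [1.0, 0.30])
        assert got_a.tolist() == [0, 0, 1]

    def test_out_of_radius_points_unassigned(self):
        v = np.array([[1.0, 0.0], [0.0, 1.0]])
        w = np.ones(2)
        # force both into one cluster whose centroid leaves p1 outside th_d
        a, c = merge(v, w, np.array([0, 1]), v.copy(), 2.0, 0.2)
        assert (a == UNASSIGNED).all()


class TestDcrawler:
    def test_separated_blobs_recover_labels(self, rng):
        centers = np.eye(4)
        v, labels = _blobs(rng, centers, 20, 0.02)
        cvs = [ColourVector(p, 1.0) for p in v]
        cs = dcrawler(cvs, 0.2)
        assert cs.n_clusters == 4
        # each blob maps to exactly one cluster
        for i in range(4):
            assert len(set(cs.assignments[labels == i])) == 1

    def test_identical_points_single_cluster(self):
        cvs = [vector_normalize((1, 2, 2)) for _ in range(10)]
        cs = dcrawler(cvs, 0.1)
        assert cs.n_clusters == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_convergence_invariants(self, seed):
        """All points within Th(d) of their centroid; centroids separated
        beyond the final merge threshold."""
        rng = np.random.default_rng(seed)
        n_dim = int(rng.integers(2, 8))
        v = rng.uniform(0, 1, size=(int(rng.integers(10, 120)), n_dim))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        th_d = float(rng.uniform(0.1, 0.5))
        cs = dcrawler([ColourVector(p, float(m)) for p, m in
                       zip(v, rng.uniform(0.1, 2.0, len(v)))], th_d)
        assert (cs.assignments >= 0).all()
        for i, p in enumerate(v):
            d = np.linalg.norm(p - cs.centroids[cs.assignments[i]])
            assert d <= th_d + 1e-9
        if cs.n_clusters > 1:
            cd = np.linalg.norm(
                cs.centroids[:, None] - cs.centroids[None], axis=2
            )
            np.fill_diagonal(cd, np.inf)
            assert cd.min() > cs.final_merge_threshold

    def test_order_stability_on_blob_data(self, rng):
        """Clustering is insensitive to input order on well-structured data."""
        from sklearn.metrics import adjusted_rand_score

        v, labels = _blobs(rng, np.eye(5), 15, 0.04)
        cvs = [ColourVector(p, 1.0) for p in v]
        base = dcrawler(cvs, 0.2).assignments
        aris = []
        for _ in range(20):
            perm = rng.permutation(len(cvs))
            out = dcrawler([cvs[i] for i in perm], 0.2).assignments
            restored = np.empty(len(cvs), dtype=int)
            restored[perm] = out
            aris.append(adjusted_rand_score(base, restored))
        assert np.mean(aris) >= 0.95

    def test_cluster_count_non_increasing_in_th_d(self, rng):
        v, _ = _blobs(rng, rng.uniform(0.1, 1, (6, 5)), 12, 0.05)
        cvs = [ColourVector(p, 1.0) for p in v]
        counts = [dcrawler(cvs, t).n_clusters for t in (0.1, 0.2, 0.4, 0.8)]
        # non-strict downward trend, one unit of slack for boundary effects
        for a, b in zip(counts, counts[1:]):
            assert b <= a + 1

    def test_phantom_colour_vectors_recover_neurons(self, rng):
        """Noisy per-neuron colour vectors at Th(d)=0.2: median F1 >= 0.9."""
        from qdyefinder.evaluation import match_and_score
        from qdyefinder.simulation import LabelModel, simulate_cells

        truth = simulate_cells(LabelModel(7, 2.0), 30, rng)
        pts, labels = [], {}
        k = 0
        for n, t in enumerate(truth):
            for _ in range(int(rng.integers(5, 15))):
                v = np.clip(t + rng.normal(0, 0.05, 7), 1e-9, None)
                pts.append(
                    ColourVector(v / np.linalg.norm(v), float(rng.uniform(0.2, 1)),
                                 fragment_id=k)
                )
                labels[k] = n
                k += 1
        cs = dcrawler(pts, 0.2)
        cluster_map = {p.fragment_id: int(c)
                       for p, c in zip(pts, cs.assignments)}
        scores = match_and_score(labels, cluster_map)
        assert np.median([s.f1 for s in scores]) >= 0.9

    def test_input_validation(self):
        with pytest.raises(ValueError):
            dcrawler([], 0.2)
        with pytest.raises(ValueError):
            dcrawler([vector_normalize((1, 0))], 0.0)

    def test_magnitude_order_option(self, rng):
        v, _ = _blobs(rng, np.eye(3), 10, 0.02)
        cvs = [ColourVector(p, float(m))
               for p, m in zip(v, rng.uniform(0.1, 2, len(v)))]
        cs = dcrawler(cvs, 0.2, order="magnitude")
        assert cs.n_clusters == 3
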