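import numpy as np
import pandas as pd
import pytest

from sodakit import soda, synthetic
from sodakit.soda import RingSet

PX = 15.0


class TestRingSet:
    def test_default_geometry(self):
        rings = RingSet()
        assert rings.n_rings == 16
        assert rings.r_max == 240.0
        assert np.array_equal(rings.radii, np.arange(17) * 15.0)

    def test_universal_threshold(self):
        # T(N) = 2 ln N with natural log: T(16) = 2 ln 16
        assert RingSet().threshold == pytest.approx(2 * np.log(16))
        assert RingSet().threshold == pytest.approx(5.5452, abs=1e-4)

    def test_ring_membership_half_open(self):
        rings = RingSet()
        assert rings.ring_index([40.0]) == 2          # 30 < 40 <= 45
        assert rings.ring_index([15.0]) == 0          # boundary: (0, 15]
        assert rings.ring_index([15.000001]) == 1
        assert rings.ring_index([0.0]) == -1
        assert rings.ring_index([240.0]) == 15
        assert rings.ring_index([250.0]) == -1


class TestPairEnumeration:
    def test_beyond_r_max_excluded(self):
        pairs = soda.pairwise_candidate_distances(
            [[0.0, 0.0]], [[250.0, 0.0]], RingSet())
        assert len(pairs) == 0

    def test_single_pair_ring(self):
        pairs = soda.pairwise_candidate_distances(
            [[0.0, 0.0]], [[40.0, 0.0]], RingSet())
        assert len(pairs) == 1
        assert pairs.iloc[0]["ring"] == 2

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        p1 = rng.uniform(0, 3000, size=(500, 2))
        p2 = rng.uniform(0, 3000, size=(500, 2))
        rings = RingSet()
        pairs = soda.pairwise_candidate_distances(p1, p2, rings)
        got = set(zip(pairs["idx1"], pairs["idx2"]))
        diff = p1[:, None, :] - p2[None, :, :]
        d = np.linalg.norm(diff, axis=2)
        want = set(zip(*np.nonzero((d > 0) & (d <= rings.r_max))))
        assert got == want


class TestEdgeCorrection:
    def test_interior_weight_one(self, full_mask):
        w = soda.edge_correction_weights(
            np.array([[3000.0, 3000.0]]), np.array([100.0]), full_mask, PX)
        assert w[0] == pytest.approx(1.0)

    def test_half_plane_weight_two(self):
        mask = np.zeros((512, 512), dtype=bool)
        mask[:, :256] = True  # ROI is the left half-plane
        center = np.array([[255 * PX, 256 * PX]])  # on the straight edge
        w = soda.edge_correction_weights(center, np.array([60.0]), mask, PX,
                                         n_angles=256)
        assert w[0] == pytest.approx(2.0, rel=0.1)

    def test_refinement_oracle(self, dendrite_mask):
        """64-angle sampling agrees with dense 4096-angle sampling."""
        rng = np.random.default_rng(3)
        pts = soda.sample_uniform_in_mask(dendrite_mask, 200, rng, PX)
        d = rng.uniform(20, 240, size=200)
        w64 = soda.edge_correction_weights(pts, d, dendrite_mask, PX,
                                           n_angles=64)
        w4096 = soda.edge_correction_weights(pts, d, dendrite_mask, PX,
                                             n_angles=4096)
        assert np.all(np.abs(w64 - w4096) / w4096 < 0.05 + 1e-12)

    def test_zero_distance_raises(self, full_mask):
        with pytest.raises(ValueError):
            soda.edge_correction_weights(np.array([[100.0, 100.0]]),
                                         np.array([0.0]), full_mask, PX)


class TestGVector:
    def test_no_pairs_zero(self):
        G = soda.compute_G_vector(np.empty(0, int), np.empty(0), 10, 10,
                                  1e6, RingSet())
        assert np.all(G == 0)

    def test_single_pair_value(self):
        G = soda.compute_G_vector(np.array([2]), np.array([1.0]), 5, 7,
                                  1e6, RingSet())
        assert G[2] == pytest.approx(1e6 / 35)
        assert np.count_nonzero(G) == 1

    def test_zero_counts_raise(self):
        with pytest.raises(ValueError, match="no clusters"):
            soda.compute_G_vector(np.empty(0, int), np.empty(0), 0, 10,
                                  1e6, RingSet())


class TestNullMoments:
    def test_analytic_mu_ring1(self, dendrite_mask):
        mu, sigma = soda.null_moments(RingSet(), dendrite_mask, PX, 200, 200,
                                      mode="analytic", n_reps=20, seed=0)
        assert mu[0] == pytest.approx(np.pi * 225.0)     # ~706.9 nm^2
        assert np.all(sigma > 0)

    def test_monte_carlo_converges_to_analytic(self, full_mask):
        mu_mc, _ = soda.null_moments(RingSet(), full_mask, PX, 800, 800,
                                     mode="monte_carlo", n_reps=500, seed=1)
        expected = np.pi * np.diff(RingSet().radii ** 2)
        assert np.all(np.abs(mu_mc - expected) / expected < 0.03)

    def test_few_reps_raise(self, full_mask):
        with pytest.raises(ValueError):
            soda.null_moments(RingSet(), full_mask, PX, 100, 100, n_reps=5)

    def test_small_counts_warn(self, full_mask):
        with pytest.warns(UserWarning, match="100"):
            soda.null_moments(RingSet(), full_mask, PX, 20, 20, n_reps=10,
                              seed=0)


class TestReduceAndThreshold:
    def test_G_equals_mu_all_zero(self):
        n = 16
        stats = soda.reduce_and_threshold(np.full(n, 5.0), np.full(n, 5.0),
                                          np.ones(n))
        assert np.all(stats.G0 == 0)
        assert not stats.significant.any()

    def test_ten_sigma_retained(self):
        n = 16
        G = np.full(n, 5.0)
        mu = np.full(n, 5.0)
        G[1] = mu[1] + 10.0
        stats = soda.reduce_and_threshold(G, mu, np.ones(n))
        assert stats.G0[1] == pytest.approx(10.0)
        assert stats.G0[1] > 2 * np.log(16)
        assert np.count_nonzero(stats.G0) == 1

    def test_idempotent(self):
        n = 16
        rng = np.random.default_rng(2)
        G = rng.uniform(0, 20, n)
        stats = soda.reduce_and_threshold(G, np.full(n, 5.0), np.ones(n))
        again = soda.reduce_and_threshold(
            stats.G0 + np.full(n, 5.0), np.full(n, 5.0), np.ones(n))
        # re-thresholding the conserved values changes nothing
        assert np.array_equal(again.G0, stats.G0)

    def test_singular_A_raises(self):
        n = 4
        with pytest.raises(np.linalg.LinAlgError):
            soda.reduce_and_threshold(np.ones(n), np.zeros(n), np.ones(n),
                                      A=np.zeros((n, n)))


class TestCouplingProbability:
    def _stats(self, G, mu):
        return soda.reduce_and_threshold(np.asarray(G, float),
                                         np.asarray(mu, float),
                                         np.ones(len(G)))

    def test_non_significant_ring_zero(self):
        stats = self._stats([5.0] * 16, [5.0] * 16)
        p = soda.pair_coupling_probabilities(stats, np.array([3]))
        assert p[0] == 0.0

    def test_algebraic_identity(self):
        # with A = I: P = (G_i - mu_i) / G_i, so G = 2 mu -> P = 0.5
        G = [5.0] * 16
        mu = [5.0] * 16
        G[4] = 200.0
        mu[4] = 100.0
        stats = self._stats(G, mu)
        p = soda.pair_coupling_probabilities(stats, np.array([4]))
        assert p[0] == pytest.approx(0.5)

    def test_clipped_to_unit_interval(self):
        G = [5.0] * 16
        mu = [5.0] * 16
        G[2] = 1000.0
        mu[2] = -10.0  # force ratio > 1
        stats = self._stats(G, mu)
        p = soda.pair_coupling_probabilities(stats, np.array([2]))
        assert p[0] == 1.0


class TestSummarize:
    def test_empty_pairs(self):
        summary = soda.summarize_coupling(pd.DataFrame(
            columns=["idx1", "idx2", "distance", "ring",
                     "coupling_probability"]), 10, 12, RingSet())
        assert summary.coupling_index_ch1 == 0.0
        assert summary.coupled_fraction_ch2 == 0.0
        assert np.all(summary.ring_pair_counts == 0)

    def test_every_cluster_coupled(self):
        pairs = pd.DataFrame({
            "idx1": np.arange(5), "idx2": np.arange(5),
            "distance": np.full(5, 40.0), "ring": np.full(5, 2),
            "coupling_probability": np.full(5, 0.9),
        })
        s = soda.summarize_coupling(pairs, 5, 5, RingSet())
        assert s.coupled_fraction_ch1 == 1.0
        assert s.coupling_index_ch1 == pytest.approx(0.9)
        assert s.mean_coupling_distance == pytest.approx(40.0)

    def test_max_pair_aggregation(self):
        pairs = pd.DataFrame({
            "idx1": [0, 0], "idx2": [0, 1],
            "distance": [40.0, 100.0], "ring": [2, 6],
            "coupling_probability": [0.3, 0.8],
        })
        s = soda.summarize_coupling(pairs, 1, 2, RingSet())
        assert s.cluster_probability_ch1[0] == 0.8
        assert s.cluster_distance_ch1[0] == 100.0


class TestEndToEnd:
    def test_dual_label_like(self):
        """Identical centroid sets with 3 nm jitter couple at ring 1."""
        cfg = synthetic.SimulationConfig(
            n_clusters_ch1=300, n_clusters_ch2=300, coupling_fraction=1.0,
            coupling_distance_mean=0.0, coupling_distance_sd=3.0, seed=8,
        )
        truth = synthetic.simulate_cluster_pairs(cfg)
        res = soda.analyze_points(truth.positions_ch1, truth.positions_ch2,
                                  truth.roi_mask, PX, seed=8)
        s = res.summary
        assert s.coupling_index_ch1 > 0.95
        assert s.coupled_fraction_ch1 > 0.95
        modal_ring = int(np.argmax(s.ring_pair_counts))
        assert modal_ring == 0
        ring1 = res.pairs[res.pairs.ring == 0]
        assert ring1.coupling_probability.mean() > 0.98

    def test_csr_false_coupling_control(self):
        """f = 0: low mean probability, rarely any significant ring."""
        n_sig = 0
        mean_ps = []
        for seed in range(25):
            cfg = synthetic.SimulationConfig(
                n_clusters_ch1=300, n_clusters_ch2=300,
                coupling_fraction=0.0, seed=100 + seed,
            )
            truth = synthetic.simulate_cluster_pairs(cfg)
            res = soda.analyze_points(truth.positions_ch1,
                                      truth.positions_ch2,
                                      truth.roi_mask, PX, seed=seed)
            n_sig += int(res.stats.significant.any())
            mean_ps.append(0.5 * (res.summary.mean_probability_ch1
                                  + res.summary.mean_probability_ch2))
        assert np.mean(mean_ps) <= 0.05
        assert n_sig / 25 <= 0.10

    def test_monotone_in_f(self):
        indices = []
        for f in (0.2, 0.5, 0.8):
            vals = []
            for seed in (0, 1):
                cfg = synthetic.SimulationConfig(
                    n_clusters_ch1=400, n_clusters_ch2=400,
                    coupling_fraction=f, coupling_distance_mean=40.0,
                    coupling_distance_sd=2.0, seed=30 + seed,
                )
                truth = synthetic.simulate_cluster_pairs(cfg)
                res = soda.analyze_points(truth.positions_ch1,
                                          truth.positions_ch2,
                                          truth.roi_mask, PX, seed=seed)
                vals.append(res.summary.coupling_index_ch1)
            indices.append(np.mean(vals))
        assert indices[0] < indices[1] < indices[2]

    def test_monte_carlo_ring_matrix_mode(self, coupled_truth):
        t = coupled_truth
        res = soda.analyze_points(t.positions_ch1, t.positions_ch2,
                                  t.roi_mask, PX, seed=1,
                                  ring_matrix="monte_carlo")
        # same qualitative result as identity mode
        assert res.summary.coupling_index_ch1 == pytest.approx(0.5, abs=0.1)
        assert not np.allclose(res.stats.A, np.eye(16))

    def test_mean_pair_probability_matches_ring_excess(self, coupled_truth):
        """Per-pair P equals the non-random pair fraction of its ring.

        Oracle: from ground truth, the expected P of a significant ring
        equals (true coupled pairs in ring) / (all pairs in ring).
        """
        t = coupled_truth
        res = soda.analyze_points(t.positions_ch1, t.positions_ch2,
                                  t.roi_mask, PX, seed=2)
        pairs = res.pairs
        truly = {(int(i), int(j)) for i, j, _ in t.coupled_pairs}
        for ring in np.flatnonzero(res.stats.significant):
            sub = pairs[pairs.ring == ring]
            if len(sub) < 30:
                continue
            frac_true = np.mean([(int(r.idx1), int(r.idx2)) in truly
                                 for r in sub.itertuples()])
            assert sub.coupling_probability.mean() == pytest.approx(
                frac_true, abs=0.15)
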