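"""Effective community size, gamma inversion, and annotation comparison."""

import numpy as np
import pytest

import hicscape as h

from conftest import random_network


def part(labels):
    return h.Partition(labels=np.asarray(labels))


class TestEffectiveSize:
    def test_uniform_sizes_perplexity_equals_count(self):
        p = part(np.repeat(np.arange(4), 5))
        s = h.effective_size(p, 100_000)
        assert s.perplexity == pytest.approx(4.0)
        assert s.effective_size_bins == pytest.approx(5.0)
        assert s.effective_size_mb == pytest.approx(0.5)

    def test_sizes_three_one(self):
        """Sizes {3,1}: H ~ 0.81128 bits, perplexity ~ 1.75480, s_hat ~ 2.2794."""
        s = h.effective_size(part([0, 0, 0, 1]), 100_000)
        assert s.entropy == pytest.approx(2 - 0.75 * np.log2(3), rel=1e-12)
        assert s.perplexity == pytest.approx(4 / 3**0.75, rel=1e-12)
        assert s.effective_size_bins == pytest.approx(3**0.75, rel=1e-12)

    def test_single_community(self):
        s = h.effective_size(part(np.zeros(7, dtype=int)), 100_000)
        assert s.perplexity == pytest.approx(1.0)
        assert s.effective_size_bins == pytest.approx(7.0)

    def test_relabeling_and_node_order_invariance(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 5, size=30)
        a = h.effective_size(part(labels), 100_000)
        perm = rng.permutation(30)
        b = h.effective_size(part(labels[perm]), 100_000)
        shift = h.effective_size(part((labels + 2) % 5), 100_000)
        assert a.perplexity == pytest.approx(b.perplexity)
        assert a.perplexity == pytest.approx(shift.perplexity)

    def test_min_size_filter_drops_small_communities(self):
        labels = np.array([0] * 10 + [1] * 10 + [2])  # one singleton
        full = h.effective_size(part(labels), 100_000)
        filtered = h.effective_size(part(labels), 100_000, min_community_bins=5)
        assert filtered.perplexity == pytest.approx(2.0)
        assert full.perplexity < 3.0 and full.perplexity > 2.0

    def test_median_reported(self):
        s = h.effective_size(part([0, 0, 0, 1]), 100_000)
        assert s.median_size_bins == pytest.approx(2.0)

    def test_perplexity_bounds(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            labels = np.random.default_rng(seed).integers(0, 6, size=40)
            s = h.effective_size(part(labels), 100_000)
            k = len(np.unique(labels))
            assert 1.0 - 1e-9 <= s.perplexity <= k + 1e-9


class TestScaleCurve:
    def test_single_gamma_grid(self, planted_instance):
        _, net, _ = planted_instance
        curve = h.scale_curve(net, 0.75, [1.0], runs_per_gamma=3, master_seed=0)
        assert len(curve.gammas) == 1
        assert curve.shat_bins[0] > 0

    def test_shat_decreases_over_wide_gamma_range(self, planted_instance):
        """Small gamma -> near-whole-network community; large gamma -> near
        block scale (20 bins) or below."""
        _, net, _ = planted_instance
        curve = h.scale_curve(
            net, 0.75, [0.05, 1.0, 8.0], runs_per_gamma=3, master_seed=1
        )
        assert curve.shat_bins[0] > curve.shat_bins[-1]
        assert curve.shat_bins[0] > 40  # towards whole-network scale
        assert curve.shat_bins[-1] < 30  # near or below planted block scale

    def test_deterministic_under_fixed_seed(self, planted_instance):
        _, net, _ = planted_instance
        a = h.scale_curve(net, 0.75, [0.5, 2.0], 3, master_seed=7)
        b = h.scale_curve(net, 0.75, [0.5, 2.0], 3, master_seed=7)
        np.testing.assert_array_equal(a.shat_bins, b.shat_bins)
        np.testing.assert_array_equal(a.q_max, b.q_max)

    def test_empty_grid_raises(self, planted_instance):
        _, net, _ = planted_instance
        with pytest.raises(ValueError, match="empty gamma grid"):
            h.scale_curve(net, 0.75, [], 2, master_seed=0)


class TestGammaForShat:
    def make_curve(self, gammas, shat_mb):
        gammas = np.asarray(gammas, dtype=float)
        shat_mb = np.asarray(shat_mb, dtype=float)
        return h.ScaleCurve(
            gammas=gammas,
            shat_bins=shat_mb * 10,
            shat_mb=shat_mb,
            q_max=np.ones_like(gammas),
            mean_distance=np.zeros_like(gammas),
            quality_cv=np.zeros_like(gammas),
        )

    def test_grid_point_target_returns_that_gamma(self):
        curve = self.make_curve([0.5, 1.0, 2.0], [8.0, 4.0, 1.0])
        assert h.gamma_for_shat(curve, 4.0) == 1.0

    def test_loglog_midpoint_interpolation(self):
        """Hand-computed: log-linear between (gamma=1, s=4) and (gamma=4, s=1)
        at s=2 gives gamma = 2."""
        curve = self.make_curve([1.0, 4.0], [4.0, 1.0])
        assert h.gamma_for_shat(curve, 2.0) == pytest.approx(2.0, rel=1e-9)

    def test_out_of_range_raises_with_range(self):
        curve = self.make_curve([0.5, 1.0], [8.0, 4.0])
        with pytest.raises(ValueError, match="achievable range"):
            h.gamma_for_shat(curve, 100.0)

    def test_non_monotonic_warns_and_uses_closest(self):
        curve = self.make_curve([0.5, 1.0, 2.0], [4.0, 6.0, 1.0])
        with pytest.warns(UserWarning, match="not monotonic"):
            g = h.gamma_for_shat(curve, 5.5)
        assert g == 1.0


class TestAnnotationToPartition:
    def track(self, intervals, res=100_000):
        return h.AnnotationTrack(chromosome="1", intervals=intervals, resolution=res)

    def test_segments_mode_toy_track(self):
        """A,A,B,B,A rasterizes to 3 segment communities {0,1},{2,3},{4}."""
        net = random_network(5, seed=1)
        track = self.track(
            [(0, 200_000, "A"), (200_000, 400_000, "B"), (400_000, 500_000, "A")]
        )
        p = h.annotation_to_partition(track, "segments", net)
        assert np.array_equal(p.labels, [0, 0, 1, 1, 2])

    def test_classes_mode_with_merge(self):
        net = random_network(5, seed=1)
        track = self.track(
            [(0, 200_000, "A1"), (200_000, 400_000, "B2"), (400_000, 500_000, "A2")]
        )
        p = h.annotation_to_partition(track, "classes", net, merge_ab=True)
        assert np.array_equal(p.labels, [0, 0, 1, 1, 0])

    def test_gap_bins_unassigned(self):
        net = random_network(6, seed=1)
        track = self.track([(0, 200_000, "T1"), (400_000, 600_000, "T2")])
        p = h.annotation_to_partition(track, "segments", net)
        assert np.array_equal(p.labels, [0, 0, -1, -1, 1, 1])

    def test_partial_coverage_rule(self):
        """A label is assigned only with >= 50% bin coverage."""
        net = random_network(3, seed=1)
        track = self.track([(0, 140_000, "A"), (140_000, 300_000, "B")])
        p = h.annotation_to_partition(track, "segments", net)
        # bin 1 is covered 40% by A, 60% by B -> B wins
        assert p.labels[0] != p.labels[1]
        assert p.labels[1] == p.labels[2]

    def test_empty_track_raises(self):
        net = random_network(3, seed=1)
        with pytest.raises(ValueError, match="empty annotation"):
            h.annotation_to_partition(self.track([]), "segments", net)

    def test_unknown_mode_raises(self):
        net = random_network(3, seed=1)
        with pytest.raises(ValueError, match="mode"):
            h.annotation_to_partition(self.track([(0, 100_000, "A")]), "blah", net)


class TestAmi:
    def test_identical_partitions_score_one(self):
        p = part([0, 0, 1, 1, 2, 2])
        assert h.ami(p, p) == pytest.approx(1.0)

    def test_label_permutation_invariance(self):
        p = part([0, 0, 1, 1, 2, 2])
        q = part([2, 2, 0, 0, 1, 1])
        assert h.ami(p, q) == pytest.approx(1.0)

    def test_independent_labelings_near_zero(self):
        """Chance correction: random labelings of 10^4 nodes -> |AMI| < 0.01."""
        rng = np.random.default_rng(0)
        p = part(rng.integers(0, 10, size=10_000))
        q = part(rng.integers(0, 10, size=10_000))
        assert abs(h.ami(p, q)) < 0.01

    def test_restricted_to_jointly_assigned_nodes(self):
        p = part([0, 0, 1, 1, -1, -1])
        q = part([1, 1, 0, 0, 0, 1])
        assert h.ami(p, q) == pytest.approx(1.0)  # only first 4 nodes compared

    def test_too_few_common_nodes_raises(self):
        p = part([0, -1, -1])
        q = part([-1, 0, 0])
        with pytest.raises(ValueError, match="fewer than 2"):
            h.ami(p, q)


class TestBestMatchScan:
    def test_synthetic_closure(self, planted_instance):
        """An annotation drawn from the planted partition is recovered with
        AMI ~ 1 at the gamma that resolves the planted blocks."""
        spec, net, planted = planted_instance
        intervals = []
        for cid, comm in enumerate(planted.communities):
            start = int(comm[0]) * net.resolution
            end = (int(comm[-1]) + 1) * net.resolution
            intervals.append((start, end, f"T{cid}"))
        track = h.AnnotationTrack("synthetic", intervals, net.resolution)
        (gamma, shat, score), report = h.best_match_scan(
            net, track, "segments", 0.75, [0.3, 1.0], 5, master_seed=2
        )
        assert score >= 0.95
        assert gamma == 1.0
        assert len(report["AMI"]) == 2

    def test_single_gamma_reduces_to_one_ami(self, planted_instance):
        spec, net, planted = planted_instance
        intervals = [
            (int(c[0]) * net.resolution, (int(c[-1]) + 1) * net.resolution, f"T{i}")
            for i, c in enumerate(planted.communities)
        ]
        track = h.AnnotationTrack("synthetic", intervals, net.resolution)
        (gamma, _, score), report = h.best_match_scan(
            net, track, "segments", 0.75, [1.0], 4, master_seed=5
        )
        assert gamma == 1.0
        assert len(report["gamma"]) == 1
        ens = h.sample_ensemble(net, 0.75, 1.0, 4, master_seed=5)
        ref = h.annotation_to_partition(track, "segments", net)
        assert score == pytest.approx(h.ami(ens.best(), ref))
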