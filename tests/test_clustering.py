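import numpy as np
import pytest

from tcrot import (
    ValidationError,
    annulus_profile,
    extract_clusters,
    fit_segmented,
    make_spikein_pair,
    score_repertoire_pair,
    self_distance_matrix,
)
from tcrot.clustering import AnnulusProfile


def profile_from_points(radii, means, step=5.0, r_max=200.0, counts=None):
    radii = np.asarray(radii, dtype=float)
    if counts is None:
        counts = np.ones(len(radii), dtype=np.int64)
    return AnnulusProfile(
        radii=radii,
        means=np.asarray(means, dtype=float),
        counts=np.asarray(counts),
        step=step,
        r_max=r_max,
    )


def elbow(radii, kink=60.0, high_slope=-2.0, low_slope=0.0, intercept=150.0):
    r = np.asarray(radii, dtype=float)
    return np.where(
        r <= kink,
        intercept + high_slope * r,
        intercept + high_slope * kink + low_slope * (r - kink),
    )


class TestAnnulusProfile:
    def make_scene(self):
        # 6 TCRs: distances from the centroid and loneliness values
        d = np.array([0.0, 2.0, 7.0, 12.0, 33.0, 250.0])
        D22 = np.abs(d[:, None] - d[None, :])  # 1-D embedding is enough
        scores = np.array([10.0, 9.0, 5.0, 4.0, 1.0, 0.5])
        return scores, D22

    def test_isolated_centroid_single_annulus(self):
        scores = np.array([3.0, 1.0])
        D22 = np.array([[0.0, 999.0], [999.0, 0.0]])
        p = annulus_profile(scores, D22, 0, step=5, r_max=200)
        assert list(p.radii) == [0.0]
        assert p.means[0] == 3.0

    def test_uniform_loneliness_constant_means(self):
        _, D22 = self.make_scene()
        p = annulus_profile(np.full(6, 7.0), D22, 0, step=5, r_max=200)
        assert np.allclose(p.means, 7.0)

    def test_semiclosed_annuli_and_means(self):
        scores, D22 = self.make_scene()
        p = annulus_profile(scores, D22, 0, step=5, r_max=100)
        # ball [0,5): {0,1}; [5,10): {2}; [10,15): {3}; [30,35): {4}
        assert list(p.radii) == [0.0, 5.0, 10.0, 30.0]
        assert p.means[0] == pytest.approx(9.5)
        assert p.means[1] == 5.0
        assert list(p.counts) == [2, 1, 1, 1]

    def test_boundary_distance_lands_in_upper_annulus(self):
        # a TCR at distance exactly 5 belongs to [5, 10), not [0, 5)
        scores = np.array([1.0, 1.0])
        D22 = np.array([[0.0, 5.0], [5.0, 0.0]])
        p = annulus_profile(scores, D22, 0, step=5, r_max=20)
        assert list(p.radii) == [0.0, 5.0]
        assert list(p.counts) == [1, 1]

    def test_active_mask_excludes_clustered(self):
        scores, D22 = self.make_scene()
        active = np.array([True, False, True, True, True, True])
        p = annulus_profile(scores, D22, 0, step=5, r_max=100, active=active)
        assert p.means[0] == 10.0  # index 1 no longer averaged in

    def test_invalid_step(self):
        scores, D22 = self.make_scene()
        with pytest.raises(ValidationError):
            annulus_profile(scores, D22, 0, step=0)


class TestSegmentedFit:
    def test_exact_kink_recovered(self):
        radii = np.arange(0.0, 200.0, 5.0)
        fit = fit_segmented(profile_from_points(radii, elbow(radii, kink=60.0)))
        assert fit.status == "ok"
        assert fit.breakpoint == pytest.approx(60.0, abs=0.5)
        assert fit.beta1 == pytest.approx(-2.0, abs=1e-3)
        assert fit.beta2 == pytest.approx(2.0, abs=1e-3)

    def test_exact_kink_off_grid(self):
        radii = np.arange(0.0, 200.0, 5.0)
        fit = fit_segmented(profile_from_points(radii, elbow(radii, kink=62.5)))
        assert fit.status == "ok"
        assert fit.breakpoint == pytest.approx(62.5, abs=2.5)

    def test_linear_data_no_breakpoint(self):
        radii = np.arange(0.0, 200.0, 5.0)
        fit = fit_segmented(profile_from_points(radii, 100.0 - 0.5 * radii))
        assert fit.status == "no-breakpoint"

    def test_constant_data_no_breakpoint(self):
        radii = np.arange(0.0, 200.0, 5.0)
        fit = fit_segmented(profile_from_points(radii, np.full(len(radii), 3.0)))
        assert fit.status == "no-breakpoint"

    def test_too_few_annuli(self):
        radii = np.arange(0.0, 20.0, 5.0)
        fit = fit_segmented(profile_from_points(radii, elbow(radii)))
        assert fit.status == "no-breakpoint"

    def test_noisy_recovery_rate(self):
        # 5% noise relative to the profile's range; recovery within +/- one
        # step in at least 90% of seeded replicates
        radii = np.arange(0.0, 200.0, 5.0)
        truth = elbow(radii, kink=60.0)
        sigma = 0.05 * (truth.max() - truth.min())
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            noisy = truth + np.random.default_rng(seed).normal(0, sigma, len(radii))
            fit = fit_segmented(profile_from_points(radii, noisy))
            if fit.status == "ok" and abs(fit.breakpoint - 60.0) <= 5.0:
                hits += 1
        assert hits >= 0.9 * n_rep


@pytest.fixture(scope="module")
def spike_scene(germline):
    src, tgt, labels = make_spikein_pair(150, 30, seed=9, table=germline)
    D22 = self_distance_matrix(tgt, germline)
    scores = score_repertoire_pair(src, tgt, germline, D22=D22)
    return scores, D22, labels


class TestExtractClusters:
    def test_rank1_cluster_recovers_spikeins(self, spike_scene):
        scores, D22, labels = spike_scene
        clusters = extract_clusters(scores, D22)
        assert len(clusters) >= 1
        members = set(clusters.clusters[0].member_indices)
        spikes = set(np.flatnonzero(labels))
        assert len(members & spikes) >= 0.9 * len(spikes)
        assert len(members - spikes) <= 0.1 * len(members)

    def test_membership_inclusive_at_breakpoint(self, spike_scene):
        scores, D22, _ = spike_scene
        clusters = extract_clusters(scores, D22)
        cl = clusters.clusters[0]
        d = D22[cl.centroid_index]
        inside = np.flatnonzero(d <= cl.breakpoint)
        assert set(cl.member_indices) == set(inside)

    def test_max_clusters_cap(self, spike_scene):
        scores, D22, _ = spike_scene
        clusters = extract_clusters(scores, D22, max_clusters=1)
        assert len(clusters) <= 1

    def test_clusters_disjoint_and_ranked(self, spike_scene):
        scores, D22, _ = spike_scene
        clusters = extract_clusters(scores, D22, max_clusters=5)
        seen = set()
        peak = np.inf
        for cl in clusters:
            assert not (set(cl.member_indices) & seen)
            seen |= set(cl.member_indices)
            centroid_score = scores.neighborhood[cl.centroid_index]
            assert centroid_score <= peak + 1e-9
            peak = centroid_score

    def test_two_planted_clusters_rank_by_loneliness(self, germline):
        import tcrot

        rng_cfg_a = tcrot.SimConfig(
            seed=21,
            n_background=0,
            n_spikein=25,
            spike_seed=tcrot.TcrBeta("TRBV19*01", "CASSIRSSYEQYF"),
            max_substitutions=1,
        )
        rng_cfg_b = tcrot.SimConfig(
            seed=22,
            n_background=0,
            n_spikein=10,
            spike_seed=tcrot.TcrBeta("TRBV28*01", "CAWSVGQGGTGELFF"),
            max_substitutions=1,
        )
        bg_cfg = tcrot.SimConfig(seed=23, n_background=100)
        a = tcrot.generate_spikein_cluster(rng_cfg_a, germline)
        b = tcrot.generate_spikein_cluster(rng_cfg_b, germline)
        bg = tcrot.generate_background(bg_cfg, germline)
        tgt = tcrot.Repertoire.from_tcrs(bg.tcrs + a.tcrs + b.tcrs)
        src = tcrot.generate_background(tcrot.SimConfig(seed=24, n_background=135), germline)
        D22 = self_distance_matrix(tgt, germline)
        scores = score_repertoire_pair(src, tgt, germline, D22=D22)
        clusters = extract_clusters(scores, D22, max_clusters=2)
        assert len(clusters) == 2
        # the larger planted cluster is denser, hence lonelier, hence rank 1
        idx_a = set(range(100, 125))
        members1 = set(clusters.clusters[0].member_indices)
        assert len(members1 & idx_a) > len(members1 - idx_a)
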