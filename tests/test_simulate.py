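"""Replication model, effective copy numbers and two-channel intensities."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import sphasecgh as sc
from .conftest import make_profile


def flat_track(probe_map, t=0.5, per_probe_domains=True):
    """A constant-timing track; one domain per probe decouples firing draws."""
    n = len(probe_map)
    dom = np.arange(n) if per_probe_domains else np.zeros(n, dtype=int)
    return sc.TimingTrack(
        probe_id=probe_map.df["probe_id"].values,
        timing=np.full(n, t),
        domain_id=dom,
        early=np.full(n, t < 0.5),
    )


class TestReplicationProbability:
    def test_half_at_equal_progression_and_timing(self):
        for tau in (0.01, 0.1, 1.0):
            assert sc.replication_probability(0.5, 0.5, sc.ReplicationModel(tau)) == 0.5

    def test_step_limit_for_small_tau(self):
        m = sc.ReplicationModel(tau=1e-6)
        assert sc.replication_probability(0.9, 0.1, m) == pytest.approx(1.0)
        assert sc.replication_probability(0.1, 0.9, m) == pytest.approx(0.0)

    def test_logistic_closed_form(self):
        m = sc.ReplicationModel(tau=0.1)
        assert sc.replication_probability(0.5, 0.3, m) == pytest.approx(
            expit(2.0), abs=1e-12
        )

    def test_monotone_in_s_and_t(self):
        m = sc.ReplicationModel(tau=0.2)
        grid = np.linspace(0, 1, 11)
        p_s = sc.replication_probability(grid, 0.5, m)
        p_t = sc.replication_probability(0.5, grid, m)
        assert (np.diff(p_s) >= 0).all() and (np.diff(p_t) <= 0).all()

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            sc.ReplicationModel(tau=0.0)
        with pytest.raises(ValueError):
            sc.ReplicationModel(tau=-1.0)


class TestEffectiveCopies:
    def test_g_phases_are_deterministic(self, small_map, diploid_xx):
        track = flat_track(small_map)
        rng = np.random.default_rng(0)
        g0 = sc.simulate_effective_copies(
            sc.CellState("g0", "G0G1", diploid_xx), small_map, track,
            sc.ReplicationModel(), rng)
        g2 = sc.simulate_effective_copies(
            sc.CellState("g2", "G2M", diploid_xx), small_map, track,
            sc.ReplicationModel(), rng)
        assert (g0 == 2).all() and (g2 == 4).all()

    def test_fully_replicated_limit(self, small_map, diploid_xx):
        track = flat_track(small_map, t=0.1)
        cell = sc.CellState("s", "S", diploid_xx, s=0.9)
        copies = sc.simulate_effective_copies(
            cell, small_map, track, sc.ReplicationModel(tau=1e-6),
            np.random.default_rng(1))
        assert (copies == 4).all()

    @pytest.mark.parametrize("s,t", [(0.3, 0.5), (0.5, 0.5), (0.7, 0.2)])
    def test_binomial_mean_recovery(self, s, t, diploid_xx):
        """Mean effective copies over many probes matches c*(1 + p(s, t))."""
        cfg = sc.MapConfig(chrom_lengths={"chr1": 900_000_000}, n_probes=10_000)
        m = sc.generate_probe_map(cfg, seed=9)
        track = flat_track(m, t=t)
        model = sc.ReplicationModel(tau=0.1, domain_weight=0.0)
        cell = sc.CellState("s", "S", diploid_xx, s=s)
        copies = sc.simulate_effective_copies(
            cell, m, track, model, np.random.default_rng(12))
        p = sc.replication_probability(s, t, model)
        se = np.sqrt(2 * p * (1 - p) / len(m))
        assert copies.mean() == pytest.approx(2 * (1 + p), abs=max(3 * se, 1e-9))

    def test_domain_sharing_correlates_probes(self, small_map, diploid_xx):
        track = sc.generate_timing_track(small_map, sc.TimingConfig(), seed=2)
        cell = sc.CellState("s", "S", diploid_xx, s=0.5)

        def within_domain_var(w):
            model = sc.ReplicationModel(tau=0.3, domain_weight=w)
            reps = [
                sc.simulate_effective_copies(
                    cell, small_map, track, model, np.random.default_rng(k))
                for k in range(30)
            ]
            arr = np.array(reps, dtype=float)
            dom = pd.Series(track.domain_id)
            # variance of domain means across replicates, averaged over domains
            means = pd.DataFrame(arr.T).groupby(dom.values).mean()
            return means.var(axis=1).mean()

        assert within_domain_var(0.9) > within_domain_var(0.0)


class TestIntensities:
    def test_noiseless_diploid_unity_ratio(self, small_map, diploid_xx):
        prof = make_profile(diploid_xx, small_map, flat_track(small_map))
        assert np.allclose(prof.log2ratio, 0.0, atol=1e-12)

    def test_noiseless_gain_ratio(self, small_map):
        region = sc.Region("g", "chr1", 1, 30_000_000, "gain")
        kt = sc.KaryotypePreset("kt", "XX", (sc.Aberration(region, 3),))
        cell = sc.CellState("c", "G0G1", kt)
        copies = sc.constitutive_copies(kt, small_map)
        table = sc.simulate_intensities(
            copies, small_map, cell, sc.NOISELESS, np.random.default_rng(0))
        ratio = table.data["test"].values / table.data["ref"].values
        in_reg = small_map.region_mask(region)
        assert np.allclose(ratio[in_reg], 1.5) and np.allclose(ratio[~in_reg], 1.0)

    def test_wga_noise_adds_in_quadrature(self, diploid_xx):
        cfg = sc.MapConfig(chrom_lengths={"chr1": 900_000_000}, n_probes=10_000)
        m = sc.generate_probe_map(cfg, seed=11)
        noise = sc.NoiseModel(sigma_wga=0.3, sigma_hyb=0.0, affinity_sd=0.0,
                              background=0.0)
        cell = sc.CellState("c", "G0G1", diploid_xx)
        copies = sc.constitutive_copies(diploid_xx, m)
        table = sc.simulate_intensities(copies, m, cell, noise,
                                        np.random.default_rng(3))
        sd = np.std(np.log2(table.data["test"].values / table.data["ref"].values))
        assert sd == pytest.approx(np.sqrt(2) * 0.3, rel=0.15)

    def test_g2m_normalizes_to_g0g1(self, small_map):
        """Uniform doubling cancels: noiseless G2/M equals G0/G1 probe-wise."""
        region = sc.Region("g", "chr1", 1, 30_000_000, "gain")
        kt = sc.KaryotypePreset("kt", "XX", (sc.Aberration(region, 3),))
        track = flat_track(small_map)
        p_g0 = make_profile(kt, small_map, track, phase="G0G1")
        p_g2 = make_profile(kt, small_map, track, phase="G2M")
        assert np.allclose(p_g0.log2ratio, p_g2.log2ratio, atol=1e-12)


class TestCohort:
    def test_counts_and_unique_ids(self, small_map, diploid_xx):
        track = flat_track(small_map)
        design = sc.CohortDesign(counts={"S": 10, "G0G1": 7}, karyotype=diploid_xx)
        cohort = sc.simulate_cohort(design, small_map, track, seed=5)
        assert len(cohort) == 17
        ids = [c.cell_id for c, _ in cohort]
        assert len(set(ids)) == 17

    def test_same_seed_identical_cohort(self, small_map, diploid_xx):
        track = flat_track(small_map)
        design = sc.CohortDesign(counts={"S": 3, "G0G1": 2}, karyotype=diploid_xx)
        a = sc.simulate_cohort(design, small_map, track, seed=5)
        b = sc.simulate_cohort(design, small_map, track, seed=5)
        for (ca, ta), (cb, tb) in zip(a, b):
            assert ca == cb
            pd.testing.assert_frame_equal(ta.data, tb.data)

    def test_s_progressions_within_range(self, small_map, diploid_xx):
        track = flat_track(small_map)
        design = sc.CohortDesign(counts={"S": 20}, karyotype=diploid_xx,
                                 s_range=(0.2, 0.4))
        cohort = sc.simulate_cohort(design, small_map, track, seed=6)
        ss = np.array([c.s for c, _ in cohort])
        assert ((ss >= 0.2) & (ss <= 0.4)).all()

    def test_oscillation_direction_in_mid_s(self, tracked_map, study_track,
                                            diploid_xx):
        """Early-replicating probes sit above late ones in a noiseless S cell."""
        prof = make_profile(diploid_xx, tracked_map, study_track, phase="S", s=0.5)
        d = prof.data[prof.data["in_norm"]]
        early = d["timing"].values < 0.5
        assert d["log2ratio"].values[early].mean() > d["log2ratio"].values[~early].mean()
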