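"""The threshold / half-probes / consecutive-run detection rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sphasecgh as sc
from .conftest import make_profile
from .test_simulate import flat_track


def profile_from_values(values, chrom="chr1"):
    """A RatioProfile with prescribed log2 ratios, one probe per 1 Mb."""
    n = len(values)
    data = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n)],
            "chrom": chrom,
            "start": np.arange(n, dtype=np.int64) * 1_000_000 + 1,
            "end": np.arange(n, dtype=np.int64) * 1_000_000 + 150_000,
            "gc": 0.4,
            "timing": 0.5,
            "log2ratio": np.asarray(values, dtype=float),
            "in_norm": True,
        }
    )
    cell = sc.CellState("fab", "S", sc.KaryotypePreset("d", "XX", ()), 0.5)
    return sc.RatioProfile(data=data, cell=cell)


def region_over(n_probes, direction="gain"):
    return sc.Region("roi", "chr1", 1, n_probes * 1_000_000, direction)


class TestProbeCalls:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.0, "neutral"), (0.31, "gain"), (-0.31, "loss"),
         (0.30, "neutral"), (-0.30, "neutral")],
    )
    def test_strict_threshold(self, value, expected):
        calls = sc.probe_calls(profile_from_values([value]), 0.3)
        assert calls[0] == expected

    def test_inclusive_mode(self):
        calls = sc.probe_calls(profile_from_values([0.30, -0.30]), 0.3, strict=False)
        assert list(calls) == ["gain", "loss"]


class TestLongestRun:
    def brute_force(self, mask):
        best = 0
        for i in range(len(mask)):
            j = i
            while j < len(mask) and mask[j]:
                j += 1
            best = max(best, j - i)
        return best

    def test_against_brute_force_scan(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            mask = rng.random(rng.integers(0, 40)) < 0.5
            assert sc.longest_run(mask) == self.brute_force(list(mask))

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.lists(st.booleans(), max_size=60))
    def test_run_bounded_by_count_and_length(self, mask):
        run = sc.longest_run(mask)
        assert run == self.brute_force(mask)
        assert run <= sum(mask) <= len(mask)


class TestEvaluateRegion:
    def make(self, k, n, run_exactly=None, direction="gain"):
        """k passing probes of n; optionally cap the longest run."""
        sign = 1.0 if direction == "gain" else -1.0
        values = np.full(n, 0.0)
        if run_exactly is None:
            values[:k] = sign * 0.6
        else:
            placed = 0
            i = 0
            while placed < k:
                take = min(run_exactly, k - placed)
                values[i : i + take] = sign * 0.6
                i += take + 1  # break the run
                placed += take
        return profile_from_values(values), region_over(n, direction)

    def test_accurate_and_reliable(self):
        prof, reg = self.make(25, 40)
        rc = sc.evaluate_region(prof, reg)
        assert (rc.k, rc.n, rc.klass, rc.reliable) == (25, 40, "accurate", True)

    def test_underestimated_below_half(self):
        prof, reg = self.make(18, 40)
        rc = sc.evaluate_region(prof, reg)
        assert rc.klass == "underestimated" and not rc.reliable

    def test_run_rule_blocks_reliability(self):
        prof, reg = self.make(20, 40, run_exactly=9)
        rc = sc.evaluate_region(prof, reg)
        assert rc.k == 20 and rc.longest_run == 9
        assert rc.klass == "accurate" and rc.reliable is False

    def test_small_region_uses_min_of_run_and_size(self):
        prof, reg = self.make(8, 8)
        rc = sc.evaluate_region(prof, reg)
        assert rc.reliable and rc.below_resolution

    def test_empty_region_is_an_error(self):
        prof = profile_from_values([0.5] * 5)
        far = sc.Region("far", "chr1", 900_000_000, 901_000_000, "gain")
        with pytest.raises(ValueError):
            sc.evaluate_region(prof, far)

    def test_k_monotone_in_threshold(self):
        rng = np.random.default_rng(23)
        prof = profile_from_values(rng.normal(0.2, 0.4, 60))
        reg = region_over(60)
        ks = [
            sc.evaluate_region(prof, reg, sc.DetectionConfig(threshold=t)).k
            for t in (0.1, 0.2, 0.3, 0.5, 0.8)
        ]
        assert (np.diff(ks) <= 0).all()


class TestEvaluateCounts:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (25, 40, "accurate"),
            (21, 42, "accurate"),       # exactly half counts as detected
            (19, 42, "underestimated"),
            (18, 40, "underestimated"),
            (10, 40, "nocall"),         # at or below a quarter of the probes
            (4, 30, "nocall"),
        ],
    )
    def test_count_rule(self, k, n, expected):
        assert sc.evaluate_counts(k, n) == expected

    def test_external_flag_overrides_rule(self):
        assert sc.evaluate_counts(8, 40, nocall_flag=False) == "underestimated"
        assert sc.evaluate_counts(13, 28, nocall_flag=True) == "nocall"
        # but the at-least-half rule is never overridden
        assert sc.evaluate_counts(25, 40, nocall_flag=True) == "accurate"


class TestClassifyCell:
    def rc(self, region, k, n, klass, direction="gain"):
        return sc.RegionCall("c", region, direction, k, n, 0, False, klass)

    def test_all_accurate(self):
        cc = sc.classify_cell("c", "S", [self.rc("a", 25, 40, "accurate"),
                                         self.rc("b", 20, 28, "accurate")])
        assert (cc.cell_class, cc.fn_subtype) == ("accurate", "none")

    def test_nocall_dominates(self):
        cc = sc.classify_cell("c", "S", [self.rc("dup", 26, 42, "accurate"),
                                         self.rc("del", 3, 28, "nocall", "loss")])
        assert (cc.cell_class, cc.fn_subtype) == ("false_negative", "no_call")

    def test_underestimation_subtype(self):
        cc = sc.classify_cell("c", "S", [self.rc("dup", 21, 42, "accurate"),
                                         self.rc("del", 13, 28, "underestimated",
                                                 "loss")])
        assert (cc.cell_class, cc.fn_subtype) == ("false_negative", "underestimation")

    def test_no_regions_is_an_error(self):
        with pytest.raises(ValueError):
            sc.classify_cell("c", "S", [])


class TestFalsePositives:
    def test_noiseless_noncarrier_counts_zero(self, small_map, diploid_xx):
        prof = make_profile(diploid_xx, small_map, flat_track(small_map))
        reg = sc.Region("r", "chr1", 1, 30_000_000, "gain")
        assert sc.false_positive_probe_count(prof, reg) == 0

    def test_huge_threshold_counts_zero(self, tracked_map, study_track, diploid_xx):
        prof = make_profile(diploid_xx, tracked_map, study_track, phase="S", s=0.5,
                            noise=sc.NoiseModel())
        reg = sc.study_regions()["dup7p"]
        assert sc.false_positive_probe_count(prof, reg, threshold=99.0) == 0

    def test_carrier_region_rejected(self, tracked_map, study_track, presets):
        prof = make_profile(presets[0], tracked_map, study_track)
        with pytest.raises(ValueError, match="carries"):
            sc.false_positive_probe_count(prof, sc.study_regions()["dup7p"])

    def test_s_cells_show_more_false_positive_pressure(self, tracked_map,
                                                       study_track, diploid_xx):
        """Replication oscillation inflates spurious in-region calls in S.

        Counted in both directions: a late-replicating region shows false
        losses in S, an early one false gains."""
        reg = sc.study_regions()["dup7p"]
        counts = {}
        for phase, s0 in (("S", 0.5), ("G0G1", None)):
            vals = []
            for rep in range(25):
                prof = make_profile(diploid_xx, tracked_map, study_track,
                                    phase=phase, s=s0, noise=sc.NoiseModel(),
                                    seed=300 + rep)
                vals.append(
                    sc.false_positive_probe_count(prof, reg, "gain")
                    + sc.false_positive_probe_count(prof, reg, "loss")
                )
            counts[phase] = np.mean(vals)
        assert counts["S"] > counts["G0G1"]
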