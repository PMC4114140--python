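"""Cell-cycle phase attribution from replication-domain oscillation.

An S-phase cell's log2 ratios oscillate with replication timing: early
domains (partially re-replicated) sit high, late domains low.  In G0/G1 (and
G2/M, whose uniform doubling normalization cancels) this wave is absent.  The
decision statistics are: a two-sided rank-sum test of early-domain vs
late-domain log2 ratios, the Spearman correlation of the ratios with
earliness (-timing), and — because early domains are GC-rich — the linear
slope of the ratios on GC content as a timing-free diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import TimingTrack
from .preprocess import RatioProfile
from .stats import rank_sum_test

__all__ = [
    "PhaseThresholds",
    "PhaseCallResult",
    "early_late_statistics",
    "classify_phase",
    "classify_cohort",
    "concordance_report",
    "concordance_rate",
]


@dataclass(frozen=True)
class PhaseThresholds:
    """Decision thresholds: significance level and minimum timing correlation.

    No published numeric criteria exist for attributing phase from the
    oscillation; these are explicit package defaults.
    """

    alpha: float = 0.01
    min_r: float = 0.2
    min_pool: int = 20  # probes required in each of the early/late pools


@dataclass(frozen=True)
class PhaseCallResult:
    cell_id: str
    early_mean: float
    late_mean: float
    u_stat: float
    p_value: float
    r_t: float        # Spearman corr of log2 ratio with -timing
    gc_slope: float   # linear slope of log2 ratio on GC fraction
    call: str = "unclassified"  # S-like | G-like | indeterminate
    reason: str = ""


def _profile_frame(profile: RatioProfile, track: TimingTrack | None) -> pd.DataFrame:
    """Autosomal probes with timing; a supplied track overrides map timing."""
    d = profile.data.loc[profile.data["in_norm"]].copy()
    if track is not None:
        lut = pd.DataFrame(
            {"probe_id": track.probe_id, "timing": track.timing}
        ).set_index("probe_id")["timing"]
        d["timing"] = lut.reindex(d["probe_id"]).values
        d = d.dropna(subset=["timing"])
    return d


def early_late_statistics(
    profile: RatioProfile,
    track: TimingTrack | None = None,
    thresholds: PhaseThresholds | None = None,
) -> PhaseCallResult:
    """Oscillation statistics of one profile; call left open for classify_phase.

    Pools autosomal log2 ratios by early (timing < 0.5) versus late domain
    and rank-sum tests the two pools; Spearman-correlates the ratios with
    earliness.  A degenerate profile (constant ratios) gives p = 1 and r = 0.
    """
    thresholds = thresholds or PhaseThresholds()
    d = _profile_frame(profile, track)
    early = d["timing"].values < 0.5
    L = d["log2ratio"].values
    cid = profile.cell.cell_id
    if early.sum() < thresholds.min_pool or (~early).sum() < thresholds.min_pool:
        return PhaseCallResult(
            cid, float("nan"), float("nan"), float("nan"), float("nan"), 0.0, 0.0,
            call="indeterminate", reason="early/late pool too small",
        )
    e_pool, l_pool = L[early], L[~early]
    res = rank_sum_test(e_pool, l_pool, mode="normal")
    if np.ptp(L) == 0 or np.ptp(d["timing"].values) == 0:
        r_t = 0.0
    else:
        r_t = float(sps.spearmanr(L, -d["timing"].values).statistic)
        if np.isnan(r_t):
            r_t = 0.0
    if np.ptp(d["gc"].values) == 0 or np.ptp(L) == 0:
        slope = 0.0
    else:
        slope = float(sps.linregress(d["gc"].values, L).slope)
    return PhaseCallResult(
        cid, float(e_pool.mean()), float(l_pool.mean()),
        res.statistic, res.pvalue, r_t, slope,
    )


def classify_phase(
    result: PhaseCallResult, thresholds: PhaseThresholds | None = None
) -> PhaseCallResult:
    """Attach the phase call: S-like needs a significant early>late wave.

    S-like iff p < alpha, r_t > min_r and early mean above late mean; G-like
    iff p >= alpha and |r_t| <= min_r; anything else (including a significant
    wave in the wrong direction) is indeterminate.
    """
    thresholds = thresholds or PhaseThresholds()
    if result.call == "indeterminate":
        return result
    p, r = result.p_value, result.r_t
    if p < thresholds.alpha and r > thresholds.min_r and (
        result.early_mean > result.late_mean
    ):
        call, reason = "S-like", ""
    elif p >= thresholds.alpha and abs(r) <= thresholds.min_r:
        call, reason = "G-like", ""
    else:
        call, reason = "indeterminate", "statistics disagree"
    return replace(result, call=call, reason=reason)


def classify_cohort(
    profiles: list[RatioProfile],
    track: TimingTrack | None = None,
    thresholds: PhaseThresholds | None = None,
) -> list[PhaseCallResult]:
    thresholds = thresholds or PhaseThresholds()
    return [
        classify_phase(early_late_statistics(p, track, thresholds), thresholds)
        for p in profiles
    ]


_TRUE_ROWS = ("S", "G")
_CALL_COLS = ("S-like", "G-like", "indeterminate")


def concordance_report(
    results: list[PhaseCallResult], true_phases: dict[str, str]
) -> pd.DataFrame:
    """2x3 confusion table: true S / G (G0G1 and G2M pooled) vs the call."""
    table = pd.DataFrame(0, index=list(_TRUE_ROWS), columns=list(_CALL_COLS))
    for res in results:
        truth = true_phases[res.cell_id]
        row = "S" if truth == "S" else "G"
        col = res.call if res.call in _CALL_COLS else "indeterminate"
        table.loc[row, col] += 1
    return table


def concordance_rate(
    results: list[PhaseCallResult], true_phases: dict[str, str]
) -> float:
    """Fraction of cells whose call matches the true phase (indeterminate counts against)."""
    if not results:
        return float("nan")
    table = concordance_report(results, true_phases)
    hits = table.loc["S", "S-like"] + table.loc["G", "G-like"]
    return float(hits / table.values.sum())
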