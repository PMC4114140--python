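"""Reference in-silico study: three carrier lines, S vs G0/G1 cohorts.

Re-creates the study design on synthetic data: the matched probe map, one
replication-timing program per cell line (timing is cell-type specific), S
and G0/G1 single-cell cohorts under default replication and noise models,
and the full analysis pipeline.  Both the acceptance script and the
simulation-level tests run the study through these entry points.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import generate_timing_track, study_presets, study_probe_map
from .phase import concordance_rate, concordance_report
from .pipeline import analyze_cohort
from .simulate import CohortDesign, simulate_cohort

__all__ = ["detection_rate_study", "concordance_study"]


def _sub(seed: int, k: int) -> int:
    return (seed * 1000 + k) & 0x7FFFFFFF


def detection_rate_study(
    seed: int, cells_per_phase: int = 100, map_seed: int = 24
) -> pd.DataFrame:
    """Per-region accurate-detection rates in S vs G0/G1 cohorts.

    Simulates ``cells_per_phase`` S and G0/G1 cells for each carrier line
    (each line gets its own timing-track realization) and tabulates, per
    region of interest, the fraction of cells in which the region class is
    ``accurate``.  Returns one row per region with the two rates and the
    G0/G1-minus-S gap.
    """
    pm = study_probe_map(seed=map_seed)
    rows = []
    for i, preset in enumerate(study_presets()):
        track = generate_timing_track(pm, seed=_sub(seed, i))
        pmt = pm.with_timing(track)
        design = CohortDesign(
            counts={"S": cells_per_phase, "G0G1": cells_per_phase},
            karyotype=preset,
        )
        cohort = simulate_cohort(design, pmt, track, seed=_sub(seed, 100 + i))
        result = analyze_cohort(cohort, pmt)
        for region, sub in result["table1a"].groupby("region"):
            entry = {"cell_line": preset.name, "region": region,
                     "size_mb": sub["size_mb"].iloc[0]}
            for phase, ss in sub.groupby("phase"):
                entry[f"rate_{phase}"] = float((ss["klass"] == "accurate").mean())
            rows.append(entry)
    df = pd.DataFrame(rows)
    df["gap"] = df["rate_G0G1"] - df["rate_S"]
    return df.sort_values("size_mb", ascending=False).reset_index(drop=True)


def concordance_study(
    seed: int, cells_per_phase: int = 50, map_seed: int = 24
) -> tuple[float, pd.DataFrame]:
    """Phase-classification concordance on a default simulated cohort.

    Simulates ``cells_per_phase`` S and G0/G1 cells of the first carrier line
    and classifies each cell's phase from its oscillation statistics.
    Returns the concordance rate and the 2x3 confusion table.
    """
    pm = study_probe_map(seed=map_seed)
    track = generate_timing_track(pm, seed=_sub(seed, 7))
    pmt = pm.with_timing(track)
    preset = study_presets()[0]
    design = CohortDesign(
        counts={"S": cells_per_phase, "G0G1": cells_per_phase}, karyotype=preset
    )
    cohort = simulate_cohort(design, pmt, track, seed=_sub(seed, 77))
    result = analyze_cohort(cohort, pmt)
    truth = {c.cell_id: c.phase for c, _ in cohort}
    from .phase import PhaseCallResult  # rebuild results from the frame

    calls = [
        PhaseCallResult(r.cell_id, r.early_mean, r.late_mean, 0.0, r.p, r.r_t,
                        r.gc_slope, call=r.call)
        for r in result["phase_calls"].itertuples()
    ]
    return concordance_rate(calls, truth), concordance_report(calls, truth)
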