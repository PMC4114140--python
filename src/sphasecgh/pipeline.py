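"""End-to-end orchestration: cohort files on disk, analysis, summary report.

A cohort directory contains ``probe_map.tsv``, ``manifest.tsv`` (cell_id,
phase, s, karyotype, seed), one ``<cell>.tsv`` intensity table per cell
(probe_id, test, ref, snr), the karyotype preset files and the resolved run
configuration, so a run is reproducible from the directory alone.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
import yaml

from . import detect as det
from . import phase as ph
from . import stats as st
from .genome import (
    KaryotypePreset,
    ProbeMap,
    TimingTrack,
    generate_timing_track,
    study_presets,
    study_probe_map,
    read_preset,
    read_probe_map,
    write_preset,
    write_probe_map,
)
from .preprocess import preprocess
from .simulate import CellState, CohortDesign, IntensityTable, simulate_cohort

__all__ = [
    "simulate_to_dir",
    "read_cohort",
    "analyze_cohort",
    "analyze_dir",
    "reproduce_table1",
    "format_table1_report",
]


def _safe(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]", "_", name)


def simulate_to_dir(
    design: CohortDesign,
    out_dir,
    seed: int,
    probe_map: ProbeMap | None = None,
    track: TimingTrack | None = None,
) -> Path:
    """Simulate a cohort and write it, its map and its resolved config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if probe_map is None:
        probe_map = study_probe_map(seed=24)
    if track is None:
        track = generate_timing_track(probe_map, seed=seed + 1)
        probe_map = probe_map.with_timing(track)
    cohort = simulate_cohort(design, probe_map, track, seed)
    write_probe_map(probe_map, out / "probe_map.tsv")
    write_preset(design.karyotype, out / f"karyotype_{_safe(design.karyotype.name)}.yaml")
    rows = []
    for cell, table in cohort:
        fname = f"{_safe(cell.cell_id)}.tsv"
        table.data.to_csv(out / fname, sep="\t", index=False)
        rows.append(
            {
                "cell_id": cell.cell_id,
                "phase": cell.phase,
                "s": "" if cell.s is None else f"{cell.s:.6f}",
                "karyotype": cell.karyotype.name,
                "file": fname,
                "seed": seed,
            }
        )
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    config = {
        "seed": seed,
        "karyotype": design.karyotype.name,
        "counts": dict(design.counts),
        "s_range": list(design.s_range),
        "mislabel_rate": design.mislabel_rate,
        "replication": {
            "tau": design.replication.tau,
            "domain_weight": design.replication.domain_weight,
        },
        "noise": {
            "sigma_wga": design.noise.sigma_wga,
            "sigma_hyb": design.noise.sigma_hyb,
            "affinity_sd": design.noise.affinity_sd,
            "background": design.noise.background,
        },
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return out


def read_cohort(cohort_dir) -> tuple[ProbeMap, list[tuple[CellState, IntensityTable]]]:
    """Load a cohort directory written by :func:`simulate_to_dir`."""
    d = Path(cohort_dir)
    manifest_path = d / "manifest.tsv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.tsv in {d}")
    probe_map = read_probe_map(d / "probe_map.tsv")
    manifest = pd.read_csv(manifest_path, sep="\t", dtype={"s": str})
    presets: dict[str, KaryotypePreset] = {p.name: p for p in study_presets()}
    for f in d.glob("karyotype_*.yaml"):
        p = read_preset(f)
        presets[p.name] = p
    cohort = []
    for _, row in manifest.iterrows():
        path = d / str(row["file"])
        if not path.exists():
            raise FileNotFoundError(f"missing cell file {path.name}")
        s_raw = row.get("s", "")
        s = None if (pd.isna(s_raw) or str(s_raw) == "") else float(s_raw)
        cell = CellState(
            str(row["cell_id"]), str(row["phase"]), presets[str(row["karyotype"])], s
        )
        data = pd.read_csv(path, sep="\t")
        cohort.append((cell, IntensityTable(data=data, cell=cell)))
    return probe_map, cohort


def analyze_cohort(
    cohort: list[tuple[CellState, IntensityTable]],
    probe_map: ProbeMap,
    det_config: det.DetectionConfig | None = None,
    thresholds: ph.PhaseThresholds | None = None,
    min_snr: float = 2.0,
) -> dict:
    """Full pipeline: preprocess, phase-classify, detect, summarize.

    Returns region calls, cell calls and phase calls as DataFrames plus the
    derived per-phase summary and the three group statistics.
    """
    det_config = det_config or det.DetectionConfig()
    thresholds = thresholds or ph.PhaseThresholds()
    profiles, cell_calls, phase_results, true_phases = [], [], [], {}
    for cell, table in cohort:
        profile = preprocess(table, probe_map, min_snr=min_snr)
        profiles.append(profile)
        true_phases[cell.cell_id] = cell.phase
        region_calls = [
            det.evaluate_region(profile, ab.region, det_config)
            for ab in cell.karyotype.aberrations
        ]
        if region_calls:
            cell_calls.append(det.classify_cell(cell.cell_id, cell.phase, region_calls))
        phase_results.append(
            ph.classify_phase(ph.early_late_statistics(profile, None, thresholds),
                              thresholds)
        )
    table1a = st.build_table1a(cell_calls)
    region_df = pd.DataFrame(
        [
            {
                "cell_id": cc.cell_id, "phase": cc.phase, "region": rc.region,
                "k": rc.k, "n": rc.n, "longest_run": rc.longest_run,
                "reliable": rc.reliable, "klass": rc.klass,
                "below_resolution": rc.below_resolution,
            }
            for cc in cell_calls for rc in cc.region_calls
        ]
    )
    cell_df = pd.DataFrame(
        [
            {"cell_id": cc.cell_id, "phase": cc.phase,
             "cell_class": cc.cell_class, "fn_subtype": cc.fn_subtype}
            for cc in cell_calls
        ]
    )
    phase_df = pd.DataFrame(
        [
            {"cell_id": r.cell_id, "early_mean": r.early_mean,
             "late_mean": r.late_mean, "p": r.p_value, "r_t": r.r_t,
             "gc_slope": r.gc_slope, "call": r.call}
            for r in phase_results
        ]
    )
    out = {
        "profiles": profiles,
        "region_calls": region_df,
        "cell_calls": cell_df,
        "phase_calls": phase_df,
        "table1a": table1a,
        "concordance": ph.concordance_report(phase_results, true_phases),
    }
    if not table1a.empty:
        table1b = st.derive_table1b(table1a)
        out["table1b"] = table1b
        if set(table1b.index) == {"S", "G0G1"}:
            try:
                out["chi2"] = st.chi_square_2x2(st.accuracy_contingency(table1b))
            except ValueError:
                pass  # degenerate table (e.g. no false negatives at all)
            out["mw_all"] = st.phase_comparison(table1a)
            out["mw_large"] = st.phase_comparison(table1a, size_filter_mb=9.0)
    return out


def analyze_dir(cohort_dir, out_dir=None, **kwargs) -> dict:
    """Analyze a cohort directory and optionally write result TSVs."""
    probe_map, cohort = read_cohort(cohort_dir)
    result = analyze_cohort(cohort, probe_map, **kwargs)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key in ("region_calls", "cell_calls", "phase_calls", "table1a"):
            result[key].to_csv(out / f"{key}.tsv", sep="\t", index=False)
        if "table1b" in result:
            result["table1b"].to_csv(out / "table1b.tsv", sep="\t")
            with open(out / "stats.txt", "w") as fh:
                fh.write(_stats_text(result))
    return result


def _stats_text(result: dict) -> str:
    lines = [str(result["table1b"]), ""]
    if "mw_all" in result:
        lines += [
            f"Mann-Whitney, all regions (fractions): p = {result['mw_all'].pvalue:.3f}",
            f"Mann-Whitney, regions > 9 Mb:          p = {result['mw_large'].pvalue:.3f}",
            f"Chi-square, accurate vs FN by phase:   p = {result['chi2'].pvalue:.3f}",
        ]
    return "\n".join(lines) + "\n"


def reproduce_table1(config: det.DetectionConfig | None = None) -> dict:
    """Reproduce the per-phase summary and statistics from the packaged table.

    Applies the at-least-half rule with the packaged no-call flags to every
    (cell, region) count, aggregates per cell and phase, and computes the
    chi-square of detection accuracy by phase and the two rank-sum
    comparisons of passing fractions (all regions; regions > 9 Mb).
    """
    fixture = st.load_table1_fixture()
    table1b = st.derive_table1b(fixture, config)
    return {
        "table1a": fixture,
        "table1b": table1b,
        "chi2": st.chi_square_2x2(st.accuracy_contingency(table1b)),
        "mw_all": st.phase_comparison(fixture),
        "mw_large": st.phase_comparison(fixture, size_filter_mb=9.0),
    }


def format_table1_report(result: dict | None = None) -> str:
    """Human-readable summary of :func:`reproduce_table1`."""
    result = result or reproduce_table1()
    b = result["table1b"]
    lines = ["Per-phase detection summary (from packaged per-cell counts)", ""]
    header = f"{'phase':8}{'underest.':>10}{'no call':>9}{'false neg.':>12}{'total':>7}"
    lines.append(header)
    for phase in ("S", "G0G1"):
        r = b.loc[phase]
        lines.append(
            f"{phase:8}{r['underestimation']:>10}{r['no_call']:>9}"
            f"{r['false_negative']:>12}{r['total_cells']:>7}"
        )
    lines += [
        "",
        f"Mann-Whitney, all regions (fractions): p = {result['mw_all'].pvalue:.3f}",
        f"Mann-Whitney, regions > 9 Mb:          p = {result['mw_large'].pvalue:.3f}",
        f"Chi-square, accurate vs FN by phase:   p = {result['chi2'].pvalue:.3f}",
    ]
    return "\n".join(lines) + "\n"
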