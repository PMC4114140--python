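"""Intensity-to-log2-ratio preprocessing: SNR filtering and normalization.

Probes with signal-to-noise strictly below the threshold (default 2) are
excluded.  Ratios are then normalized so that the *ratio of the means* of the
two channels equals 1 — the scale is a single global factor, computed over
autosomal probes by default because the reference DNA is of the opposite sex
and X/Y would otherwise bias it.  No GC-wave or replication-domain correction
is applied by default; ``wave_correction`` exists as a hook but is off, since
such corrections have not been shown to recover S-phase detection losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import ProbeMap
from .simulate import CellState, IntensityTable

__all__ = ["RatioProfile", "snr_filter", "normalize_ratios", "preprocess"]


class EmptyProfileError(ValueError):
    """All probes of a cell were excluded."""


@dataclass
class RatioProfile:
    """Normalized per-probe log2 ratios for one cell.

    ``data`` columns: probe_id, chrom, start, end, gc, timing, log2ratio and
    ``in_norm`` (probe entered the normalization mean).  ``excluded`` records
    dropped probes with a reason.  After normalization the ratio of channel
    means over the normalization set is exactly 1 (note this is not the same
    as the mean of the per-probe ratios being 1).
    """

    data: pd.DataFrame
    cell: CellState
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["probe_id", "reason"])
    )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def log2ratio(self) -> np.ndarray:
        return self.data["log2ratio"].values


def snr_filter(table: IntensityTable, min_snr: float = 2.0) -> IntensityTable:
    """Drop probes with signal-to-noise strictly below ``min_snr``.

    A probe at exactly the threshold is retained.  Raises
    :class:`EmptyProfileError` if nothing survives.
    """
    keep = table.data["snr"].values >= min_snr
    if not keep.any():
        raise EmptyProfileError(
            f"empty profile: all {len(table.data)} probes below SNR {min_snr}"
        )
    return IntensityTable(data=table.data.loc[keep].reset_index(drop=True),
                          cell=table.cell)


def normalize_ratios(
    table: IntensityTable,
    probe_map: ProbeMap,
    autosomes_only: bool = True,
    wave_correction=None,
) -> RatioProfile:
    """Normalize so the ratio of channel means equals 1; return log2 ratios.

    ``L_p = log2(test_p / ref_p) - log2(mean(test) / mean(ref))`` with the
    means taken over the normalization set (autosomes unless
    ``autosomes_only=False``).  Non-positive intensities are an error naming
    the offending probe.
    """
    df = table.data.merge(
        probe_map.df[["probe_id", "chrom", "start", "end", "gc", "timing"]],
        on="probe_id",
        how="left",
        validate="one_to_one",
    )
    if df["chrom"].isna().any():
        missing = df.loc[df["chrom"].isna(), "probe_id"].iloc[0]
        raise ValueError(f"probe {missing} not present in the probe map")
    from .genome import SEX_CHROMS

    in_norm = (
        ~df["chrom"].isin(SEX_CHROMS).values
        if autosomes_only
        else np.ones(len(df), dtype=bool)
    )
    bad = (df["test"].values <= 0) | (df["ref"].values <= 0)
    if (bad & in_norm).any():
        raise ValueError(
            f"non-positive intensity at probe "
            f"{df.loc[bad & in_norm, 'probe_id'].iloc[0]}"
        )
    dropped = pd.DataFrame(
        {"probe_id": df.loc[bad, "probe_id"].values, "reason": "non-positive intensity"}
    )
    if bad.any():
        # a sex-mismatch design can give zero signal on X/Y; exclude, don't fail
        df = df.loc[~bad].reset_index(drop=True)
        in_norm = in_norm[~bad]
    if not in_norm.any():
        raise EmptyProfileError("no probes available for normalization")
    scale = df.loc[in_norm, "test"].mean() / df.loc[in_norm, "ref"].mean()
    ratio = df["test"].values / df["ref"].values / scale
    df["log2ratio"] = np.log2(ratio)
    df["in_norm"] = in_norm
    if wave_correction is not None:
        df["log2ratio"] = wave_correction(df)
    out = df[
        ["probe_id", "chrom", "start", "end", "gc", "timing", "log2ratio", "in_norm"]
    ].copy()
    return RatioProfile(data=out, cell=table.cell, excluded=dropped)


def preprocess(
    table: IntensityTable,
    probe_map: ProbeMap,
    min_snr: float = 2.0,
    autosomes_only: bool = True,
) -> RatioProfile:
    """SNR-filter then normalize; records excluded probes with their reason."""
    kept = snr_filter(table, min_snr=min_snr)
    dropped = table.data.loc[table.data["snr"].values < min_snr, ["probe_id"]].copy()
    dropped["reason"] = f"snr<{min_snr:g}"
    profile = normalize_ratios(kept, probe_map, autosomes_only=autosomes_only)
    profile.excluded = pd.concat([dropped, profile.excluded], ignore_index=True)
    return profile
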