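"""Segmental-imbalance detection: the threshold / half-probes / run rule.

A probe calls a gain when its log2 ratio exceeds +0.3 and a loss below -0.3
(strict comparisons by default).  A region of interest is *reliably* detected
in its full length when at least half of its probes call the expected
direction with a minimum of 10 consecutive probes doing so.  Per region the
outcome is classed ``accurate`` (at least half the probes), ``nocall`` (at or
below the no-call fraction, default a quarter) or ``underestimated`` in
between; a cell is a false negative as soon as one of its constitutive
regions is not accurate, and a no-call anywhere dominates the subtype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genome import Region
from .preprocess import RatioProfile

__all__ = [
    "DetectionConfig",
    "RegionCall",
    "CellCall",
    "probe_calls",
    "longest_run",
    "evaluate_counts",
    "evaluate_region",
    "classify_cell",
    "false_positive_probe_count",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Detection rule parameters (log2 units / probe fractions)."""

    threshold: float = 0.3
    min_fraction: float = 0.5
    min_run: int = 10
    nocall_fraction: float = 0.25
    strict: bool = True  # strict inequalities at the threshold

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if not 0 < self.nocall_fraction < self.min_fraction <= 1:
            raise ValueError("require 0 < nocall_fraction < min_fraction <= 1")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


@dataclass(frozen=True)
class RegionCall:
    """Detection outcome for one (cell, region)."""

    cell_id: str
    region: str
    direction: str
    k: int              # probes passing the threshold in the expected direction
    n: int              # probes in the region
    longest_run: int    # longest streak of consecutive passing probes
    reliable: bool      # k- and run-criteria both met
    klass: str          # accurate | underestimated | nocall
    below_resolution: bool = False  # region smaller than the run requirement

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError("need 0 <= k <= n")
        if self.longest_run > self.k:
            raise ValueError("longest_run cannot exceed k")
        if self.reliable and self.klass != "accurate":
            raise ValueError("a reliable region call must be accurate")


@dataclass(frozen=True)
class CellCall:
    """Cell-level aggregation of its constitutive region calls."""

    cell_id: str
    phase: str
    region_calls: tuple[RegionCall, ...]
    cell_class: str   # accurate | false_negative
    fn_subtype: str   # underestimation | no_call | none


def probe_calls(
    profile: RatioProfile, threshold: float = 0.3, strict: bool = True
) -> np.ndarray:
    """Per-probe ternary call: gain above +threshold, loss below -threshold."""
    L = profile.log2ratio
    if strict:
        gain, loss = L > threshold, L < -threshold
    else:
        gain, loss = L >= threshold, L <= -threshold
    out = np.full(len(L), "neutral", dtype=object)
    out[gain] = "gain"
    out[loss] = "loss"
    return out


def longest_run(mask) -> int:
    """Length of the longest run of True values."""
    best = cur = 0
    for m in np.asarray(mask, dtype=bool):
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


def evaluate_counts(
    k: int, n: int, config: DetectionConfig | None = None,
    nocall_flag: bool | None = None,
) -> str:
    """Region class from counts alone (no run structure).

    ``accurate`` iff ``k >= ceil(n * min_fraction)`` (at-least-half is
    inclusive); ``nocall`` iff ``k <= floor(n * nocall_fraction)`` — unless an
    externally supplied flag overrides the no-call rule entirely, as when
    reproducing published per-cell flags that no counts-only cutoff explains.
    """
    config = config or DetectionConfig()
    if n < 1:
        raise ValueError("region must contain at least one probe")
    if k >= math.ceil(n * config.min_fraction):
        return "accurate"
    if nocall_flag is not None:
        return "nocall" if nocall_flag else "underestimated"
    if k <= math.floor(n * config.nocall_fraction):
        return "nocall"
    return "underestimated"


def evaluate_region(
    profile: RatioProfile,
    region: Region,
    config: DetectionConfig | None = None,
    nocall_flag: bool | None = None,
) -> RegionCall:
    """Apply the detection rule to one region of one cell's profile.

    ``reliable`` additionally requires ``min(min_run, n)`` consecutive passing
    probes, so a region with fewer probes than the run requirement can still
    be called but is flagged ``below_resolution``.
    """
    config = config or DetectionConfig()
    d = profile.data
    mid = (d["start"].values + d["end"].values) // 2
    sel = (
        (d["chrom"].values == region.chrom)
        & (mid >= region.start)
        & (mid <= region.end)
    )
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"region {region.name} has no retained probe")
    calls = probe_calls(profile, config.threshold, config.strict)
    passing = calls[sel] == region.direction
    k = int(passing.sum())
    run = longest_run(passing)
    reliable = k >= math.ceil(n * config.min_fraction) and run >= min(config.min_run, n)
    klass = evaluate_counts(k, n, config, nocall_flag)
    return RegionCall(
        cell_id=profile.cell.cell_id,
        region=region.name,
        direction=region.direction,
        k=k,
        n=n,
        longest_run=run,
        reliable=reliable and klass == "accurate",
        klass=klass,
        below_resolution=n < config.min_run,
    )


def classify_cell(
    cell_id: str, phase: str, region_calls: list[RegionCall] | tuple[RegionCall, ...]
) -> CellCall:
    """A cell is accurate iff every constitutive region is accurate.

    Among false negatives, a no-call in any region dominates underestimation.
    """
    if not region_calls:
        raise ValueError("cell needs at least one region call")
    klasses = [rc.klass for rc in region_calls]
    if all(kl == "accurate" for kl in klasses):
        cls, sub = "accurate", "none"
    elif "nocall" in klasses:
        cls, sub = "false_negative", "no_call"
    else:
        cls, sub = "false_negative", "underestimation"
    return CellCall(cell_id, phase, tuple(region_calls), cls, sub)


def false_positive_probe_count(
    profile: RatioProfile,
    region: Region,
    direction: str | None = None,
    threshold: float = 0.3,
    strict: bool = True,
) -> int:
    """Probes inside ``region`` that call an imbalance in a non-carrier cell.

    The cell's karyotype must lack an aberration over the region; counting how
    many of its probes still pass the threshold measures the false-positive
    pressure that S-phase oscillation puts on this region.
    """
    direction = direction or region.direction
    for ab in profile.cell.karyotype.aberrations:
        r = ab.region
        if r.chrom == region.chrom and r.start <= region.end and region.start <= r.end:
            raise ValueError(
                f"cell {profile.cell.cell_id} carries an aberration over {region.name}"
            )
    d = profile.data
    mid = (d["start"].values + d["end"].values) // 2
    sel = (
        (d["chrom"].values == region.chrom)
        & (mid >= region.start)
        & (mid <= region.end)
    )
    calls = probe_calls(profile, threshold, strict)
    return int((calls[sel] == direction).sum())
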