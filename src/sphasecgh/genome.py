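"""Genomic coordinate system: BAC probe maps, regions, karyotypes, timing tracks.

Everything downstream (simulation, normalization, detection) is expressed per
probe of a :class:`ProbeMap`.  Coordinates are 1-based closed intervals, the
cytogenetics convention; a probe belongs to a region iff its interval midpoint
falls inside the region, which avoids double-assignment of long BAC clones at
region boundaries.

Replication timing ``t`` is a per-probe value in [0, 1] (0 = replicates at the
very start of S phase, 1 = at the very end).  Contiguous probes form
replication domains with a shared domain-level timing; a domain is labelled
*early* iff its probes' timing is below 0.5.  GC content is generated
positively correlated with earliness (early domains are GC-rich), which is
what makes a GC-trend diagnostic of S phase possible.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

__all__ = [
    "Region",
    "Aberration",
    "KaryotypePreset",
    "TimingTrack",
    "ProbeMap",
    "MapConfig",
    "TimingConfig",
    "generate_probe_map",
    "generate_timing_track",
    "study_probe_map",
    "study_presets",
    "study_regions",
    "probes_in_region",
    "read_probe_map",
    "write_probe_map",
    "read_preset",
    "write_preset",
    "EmptyRegionError",
    "DEFAULT_CHROM_LENGTHS",
]

#: Approximate human chromosome lengths in base pairs (autosomes 1-22, X, Y).
DEFAULT_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 249_000_000, "chr2": 243_000_000, "chr3": 198_000_000,
    "chr4": 191_000_000, "chr5": 181_000_000, "chr6": 171_000_000,
    "chr7": 159_000_000, "chr8": 146_000_000, "chr9": 141_000_000,
    "chr10": 136_000_000, "chr11": 135_000_000, "chr12": 134_000_000,
    "chr13": 115_000_000, "chr14": 107_000_000, "chr15": 103_000_000,
    "chr16": 90_000_000, "chr17": 81_000_000, "chr18": 78_000_000,
    "chr19": 59_000_000, "chr20": 63_000_000, "chr21": 48_000_000,
    "chr22": 51_000_000, "chrX": 155_000_000, "chrY": 59_000_000,
}

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


class EmptyRegionError(ValueError):
    """Raised when a region of interest contains no probe of the active map."""


@dataclass(frozen=True)
class Region:
    """A genomic region of interest with an expected imbalance direction."""

    name: str
    chrom: str
    start: int
    end: int
    direction: str  # "gain" or "loss"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.name}: start > end")
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"region {self.name}: direction must be gain/loss")

    @property
    def size_mb(self) -> float:
        return (self.end - self.start + 1) / 1e6


@dataclass(frozen=True)
class Aberration:
    """A constitutive copy-number change over a region (cn != 2)."""

    region: Region
    cn: int

    def __post_init__(self) -> None:
        if self.cn == 2 or self.cn < 0:
            raise ValueError("aberration copy number must be a non-negative integer != 2")


@dataclass(frozen=True)
class KaryotypePreset:
    """Constitutive karyotype of a cell line: baseline 2 on autosomes plus aberrations."""

    name: str
    sex: str  # "XX" or "XY"
    aberrations: tuple[Aberration, ...] = ()

    def __post_init__(self) -> None:
        if self.sex not in ("XX", "XY"):
            raise ValueError("sex must be XX or XY")
        abrs = sorted(self.aberrations, key=lambda a: (a.region.chrom, a.region.start))
        for a, b in zip(abrs, abrs[1:]):
            if a.region.chrom == b.region.chrom and b.region.start <= a.region.end:
                raise ValueError(f"preset {self.name}: overlapping aberrations")

    @property
    def regions(self) -> tuple[Region, ...]:
        return tuple(a.region for a in self.aberrations)


@dataclass
class TimingTrack:
    """Per-probe replication timing with its domain segmentation.

    Arrays are aligned with the probe order of the map the track was built
    from; ``probe_id`` is carried so profiles that lost probes (SNR filtering)
    can still be joined against the track.
    """

    probe_id: np.ndarray
    timing: np.ndarray
    domain_id: np.ndarray
    early: np.ndarray  # bool, timing < 0.5

    def __post_init__(self) -> None:
        t = np.asarray(self.timing, dtype=float)
        if t.size and (t.min() < 0 or t.max() > 1):
            raise ValueError("timing values must lie in [0, 1]")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.probe_id,
                "timing": self.timing,
                "domain_id": self.domain_id,
                "early": self.early,
            }
        )


class ProbeMap:
    """Ordered, non-overlapping BAC probes with GC and replication timing.

    Wraps a DataFrame with columns ``chrom, start, end, probe_id, gc, timing``
    sorted by chromosome (map order) then start.
    """

    COLUMNS = ("chrom", "start", "end", "probe_id", "gc", "timing")

    def __init__(self, df: pd.DataFrame, chrom_order: list[str] | None = None):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"probe map missing columns: {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        if chrom_order is None:
            chrom_order = list(dict.fromkeys(df["chrom"]))
        self.chrom_order = [c for c in chrom_order if c in set(df["chrom"])]
        rank = {c: i for i, c in enumerate(self.chrom_order)}
        df["_rank"] = df["chrom"].map(rank)
        df = df.sort_values(["_rank", "start"], kind="mergesort").drop(columns="_rank")
        df = df.reset_index(drop=True)
        self._validate(df)
        self.df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if (df["start"] > df["end"]).any():
            raise ValueError("probe with start > end")
        if ((df["gc"] < 0) | (df["gc"] > 1)).any():
            raise ValueError("gc out of [0, 1]")
        t = df["timing"]
        if ((t < 0) | (t > 1)).any():
            raise ValueError("timing out of [0, 1]")
        if df["probe_id"].duplicated().any():
            raise ValueError("duplicate probe_id")
        for _, sub in df.groupby("chrom", sort=False):
            if (sub["start"].values[1:] <= sub["end"].values[:-1]).any():
                raise ValueError("overlapping probes within a chromosome")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def midpoints(self) -> np.ndarray:
        return ((self.df["start"].values + self.df["end"].values) // 2).astype(np.int64)

    @property
    def autosomal(self) -> np.ndarray:
        """Boolean mask of autosomal probes (sex chromosomes excluded)."""
        return ~self.df["chrom"].isin(SEX_CHROMS).values

    def with_timing(self, track: TimingTrack) -> "ProbeMap":
        df = self.df.copy()
        lut = pd.Series(track.timing, index=track.probe_id)
        df["timing"] = lut.reindex(df["probe_id"]).values
        return ProbeMap(df, chrom_order=self.chrom_order)

    def region_mask(self, region: Region) -> np.ndarray:
        """Boolean mask: probe midpoint inside [region.start, region.end]."""
        mid = self.midpoints
        return (
            (self.df["chrom"].values == region.chrom)
            & (mid >= region.start)
            & (mid <= region.end)
        )


def probes_in_region(probe_map: ProbeMap, region: Region) -> pd.DataFrame:
    """Probes of ``probe_map`` whose midpoint lies in ``region`` (map order)."""
    if region.chrom not in set(probe_map.df["chrom"]):
        raise EmptyRegionError(f"chromosome {region.chrom} absent from map")
    sub = probe_map.df.loc[probe_map.region_mask(region)]
    if sub.empty:
        raise EmptyRegionError(f"region {region.name} contains no probe")
    return sub


# ---------------------------------------------------------------------------
# Synthetic map generation
# ---------------------------------------------------------------------------


@dataclass
class MapConfig:
    """Parameters for a 24sure-like BAC array layout.

    ``enrichment`` boosts probe density in the terminal ``terminal_fraction``
    of each chromosome end, mimicking the pericentromeric/subtelomeric
    enrichment of PGD arrays.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    n_probes: int = 3000
    enrichment: float = 2.0
    terminal_fraction: float = 0.10
    probe_length: int = 150_000
    gc_mean: float = 0.41
    gc_sd: float = 0.05
    gc_corr_length_mb: float = 2.0

    def __post_init__(self) -> None:
        if self.n_probes <= 0:
            raise ValueError("n_probes must be positive")
        if self.enrichment < 1:
            raise ValueError("enrichment must be >= 1")
        if not 0 < self.terminal_fraction < 0.5:
            raise ValueError("terminal_fraction must be in (0, 0.5)")


@dataclass
class TimingConfig:
    """Replication-domain structure and its coupling to GC content.

    ``rho`` is the target correlation between GC and earliness (-timing);
    ``jitter_sd`` is the within-domain probe-level timing spread.  Jitter is
    drawn uniform on +/-1.5*jitter_sd so two probes of one domain can differ
    by at most 3*jitter_sd, deterministically.
    """

    domain_mb: float = 1.0
    min_domain_mb: float = 0.2
    max_domain_mb: float = 5.0
    jitter_sd: float = 0.02
    rho: float = 0.6

    def __post_init__(self) -> None:
        if not -1 <= self.rho <= 1:
            raise ValueError("rho must be in [-1, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if not 0 < self.min_domain_mb <= self.domain_mb <= self.max_domain_mb:
            raise ValueError("require 0 < min_domain_mb <= domain_mb <= max_domain_mb")


def _allocate(counts_total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of ``counts_total`` items by weight."""
    quota = counts_total * weights / weights.sum()
    base = np.floor(quota).astype(int)
    rem = counts_total - base.sum()
    order = np.argsort(-(quota - base), kind="mergesort")
    base[order[:rem]] += 1
    return base


def _terminal_inverse_cdf(u: np.ndarray, length: int, tf: float, e: float) -> np.ndarray:
    """Positions for quantiles ``u`` under an end-enriched piecewise density."""
    t = tf * length
    interior = length - 2 * t
    mass = np.array([e * t, interior, e * t])
    cum = np.concatenate([[0.0], np.cumsum(mass)])
    total = cum[-1]
    m = u * total
    pos = np.empty_like(m)
    seg0 = m < cum[1]
    seg2 = m >= cum[2]
    seg1 = ~(seg0 | seg2)
    pos[seg0] = m[seg0] / e
    pos[seg1] = t + (m[seg1] - cum[1])
    pos[seg2] = (length - t) + (m[seg2] - cum[2]) / e
    return pos


def generate_probe_map(config: MapConfig, seed: int) -> ProbeMap:
    """Generate a sorted, non-overlapping probe map; deterministic given seed.

    Probe midpoints are placed at jittered quantiles of an end-enriched
    density, so terminal probe density is ~``enrichment`` times the interior
    density.  GC content follows an AR(1) process along each chromosome and
    timing is attached with the default :class:`TimingConfig`.
    """
    rng = np.random.default_rng(seed)
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    n_per = _allocate(config.n_probes, lengths)
    frames = []
    for chrom, length, n in zip(chroms, lengths.astype(int), n_per):
        if n == 0:
            continue
        if 2 * n > length:
            raise ValueError(
                f"{chrom}: {n} probes cannot be placed without overlap on {length} bp"
            )
        u = (np.arange(n) + 0.5 + rng.uniform(-0.3, 0.3, size=n)) / n
        mids = _terminal_inverse_cdf(
            u, length, config.terminal_fraction, config.enrichment
        ).astype(np.int64)
        mids = np.maximum.accumulate(mids + np.arange(n))  # force strict increase
        mids = np.clip(mids, 1, length)
        gaps = np.diff(mids, prepend=mids[0] - 2 * config.probe_length,
                       append=mids[-1] + 2 * config.probe_length)
        half = np.minimum.reduce(
            [np.full(n, config.probe_length / 2), 0.45 * gaps[:-1], 0.45 * gaps[1:]]
        ).astype(np.int64)
        half = np.maximum(half, 0)
        # AR(1) GC along the chromosome
        d_mb = np.diff(mids) / 1e6
        a = np.exp(-d_mb / config.gc_corr_length_mb)
        g = np.empty(n)
        g[0] = rng.standard_normal()
        eps = rng.standard_normal(n - 1) if n > 1 else np.empty(0)
        for i in range(1, n):
            g[i] = a[i - 1] * g[i - 1] + np.sqrt(1 - a[i - 1] ** 2) * eps[i - 1]
        gc = np.clip(config.gc_mean + config.gc_sd * g, 0.2, 0.8)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": np.maximum(mids - half, 1),
                    "end": np.minimum(mids + half, length),
                    "probe_id": "",
                    "gc": gc,
                    "timing": 0.5,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df["probe_id"] = [f"bac{i:05d}" for i in range(len(df))]
    pmap = ProbeMap(df, chrom_order=chroms)
    track = generate_timing_track(pmap, TimingConfig(), seed=int(rng.integers(2**31)))
    return pmap.with_timing(track)


def generate_timing_track(
    probe_map: ProbeMap, config: TimingConfig | None = None, seed: int = 0
) -> TimingTrack:
    """Segment the map into replication domains and draw their timing.

    Domain lengths are exponential with mean ``domain_mb``, clipped to the
    configured bounds.  The domain timing is a probit transform of a Gaussian
    score correlated (coefficient ``rho``) with the standardized mean GC of
    the domain's probes, so GC-rich domains replicate early.
    """
    config = config or TimingConfig()
    rng = np.random.default_rng(seed)
    df = probe_map.df
    gc = df["gc"].values
    gc_mu, gc_sd = float(np.mean(gc)), float(np.std(gc)) or 1.0
    timing = np.empty(len(df))
    domain_id = np.empty(len(df), dtype=np.int64)
    next_dom = 0
    for chrom, sub in df.groupby("chrom", sort=False):
        idx = sub.index.values
        mids = ((sub["start"].values + sub["end"].values) // 2).astype(np.int64)
        length = int(sub["end"].values.max())
        # lay domain boundaries across the chromosome
        bounds = [0]
        while bounds[-1] < length:
            span = float(
                np.clip(
                    rng.exponential(config.domain_mb),
                    config.min_domain_mb,
                    config.max_domain_mb,
                )
            )
            bounds.append(bounds[-1] + span * 1e6)
        bounds = np.asarray(bounds)
        dom_of_probe = np.searchsorted(bounds, mids, side="right") - 1
        for d in np.unique(dom_of_probe):
            sel = idx[dom_of_probe == d]
            z = (np.mean(gc[sel]) - gc_mu) / gc_sd
            w = config.rho * z + np.sqrt(1 - config.rho**2) * rng.standard_normal()
            t_dom = float(norm.cdf(-w))
            jit = rng.uniform(
                -1.5 * config.jitter_sd, 1.5 * config.jitter_sd, size=sel.size
            )
            timing[sel] = np.clip(t_dom + jit, 0.0, 1.0)
            domain_id[sel] = next_dom + int(d)
        next_dom += len(bounds)
    return TimingTrack(
        probe_id=df["probe_id"].values.copy(),
        timing=timing,
        domain_id=domain_id,
        early=timing < 0.5,
    )


# ---------------------------------------------------------------------------
# In-study cell lines: regions, presets and the matched probe map
# ---------------------------------------------------------------------------


def study_regions() -> dict[str, Region]:
    """The five constitutive regions of the three study cell lines.

    dup7p is the interstitial 25.16 Mb duplication of 7p14.3-p21.3; the other
    four are terminal segments from the two unbalanced translocations.
    """
    return {
        "dup7p": Region("dup7p", "chr7", 7_200_001, 32_360_000, "gain"),
        "dup9p": Region("dup9p", "chr9", 1, 24_000_000, "gain"),
        "del18p": Region("del18p", "chr18", 1, 8_000_000, "loss"),
        "dup18p": Region("dup18p", "chr18", 1, 9_300_000, "gain"),
        "del20p": Region("del20p", "chr20", 1, 1_700_000, "loss"),
    }


def study_presets() -> list[KaryotypePreset]:
    """The three carrier cell lines as karyotype presets."""
    r = study_regions()
    return [
        KaryotypePreset(
            "dup7p_line", "XX", (Aberration(r["dup7p"], 3),)
        ),
        KaryotypePreset(
            "der18_t9_18_line", "XX",
            (Aberration(r["dup9p"], 3), Aberration(r["del18p"], 1)),
        ),
        KaryotypePreset(
            "der20_t18_20_line", "XY",
            (Aberration(r["dup18p"], 3), Aberration(r["del20p"], 1)),
        ),
    ]


#: exact probe counts the matched map must place in each study window
_STUDY_WINDOWS = (
    ("chr7", 7_200_001, 32_360_000, 40),
    ("chr9", 1, 24_000_000, 42),
    ("chr18", 1, 8_000_000, 28),
    ("chr18", 8_000_001, 9_300_000, 2),  # dup18p (9.3 Mb) minus del18p (8 Mb)
    ("chr20", 1, 1_700_000, 8),
)


def study_probe_map(seed: int = 24, n_probes: int = 3000) -> ProbeMap:
    """A synthetic 24sure-like map matched to the published region probe counts.

    The array's true clone coordinates are proprietary; only the probe totals
    of the five regions of interest (40, 42, 28, 30, 8) are published, so a
    generic map is generated and the probes inside each study window are
    replaced by the exact published number, evenly spaced.  The study windows
    lie in gene-poor p-arm bands, so their probes draw GC from the AT-rich
    end of the genome distribution; through the GC-timing coupling this makes
    the windows lean late-replicating, which is what exposes them to S-phase
    masking.
    """
    cfg = MapConfig(n_probes=n_probes)
    base = generate_probe_map(cfg, seed=seed)
    rng = np.random.default_rng([seed, 7001])
    df = base.df.copy()
    keep = np.ones(len(df), dtype=bool)
    inserts = []
    for chrom, start, end, m in _STUDY_WINDOWS:
        overlaps = (
            (df["chrom"].values == chrom)
            & (df["end"].values >= start)
            & (df["start"].values <= end)
        )
        keep &= ~overlaps
        span = end - start + 1
        spacing = span / m
        mids = (start + (np.arange(m) + 0.5) * spacing).astype(np.int64)
        half = int(min(cfg.probe_length / 2, 0.45 * spacing))
        inserts.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": mids - half,
                    "end": mids + half,
                    "probe_id": "",
                    "gc": np.clip(rng.normal(0.36, 0.03, size=m), 0.2, 0.8),
                    "timing": 0.5,
                }
            )
        )
    df = pd.concat([df.loc[keep]] + inserts, ignore_index=True)
    rank = {c: i for i, c in enumerate(base.chrom_order)}
    df = df.sort_values(
        ["chrom", "start"], key=lambda s: s.map(rank) if s.name == "chrom" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    df["probe_id"] = [f"bac{i:05d}" for i in range(len(df))]
    pmap = ProbeMap(df, chrom_order=base.chrom_order)
    track = generate_timing_track(pmap, TimingConfig(), seed=seed + 1)
    return pmap.with_timing(track)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_probe_map(probe_map: ProbeMap, path) -> None:
    """BED-like TSV with header: chrom, start, end, probe_id, gc, timing."""
    with open(path, "w") as fh:
        fh.write("# BAC probe map (1-based closed intervals)\n")
        probe_map.df.to_csv(fh, sep="\t", index=False)


def read_probe_map(path) -> ProbeMap:
    with open(path) as fh:
        text = "".join(line for line in fh if not line.startswith("#"))
    df = pd.read_csv(io.StringIO(text), sep="\t")
    return ProbeMap(df)


def write_preset(preset: KaryotypePreset, path) -> None:
    doc = {
        "name": preset.name,
        "sex": preset.sex,
        "aberrations": [
            {
                "name": a.region.name,
                "chrom": a.region.chrom,
                "start": int(a.region.start),
                "end": int(a.region.end),
                "direction": a.region.direction,
                "cn": int(a.cn),
            }
            for a in preset.aberrations
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_preset(path) -> KaryotypePreset:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    abrs = tuple(
        Aberration(
            Region(a["name"], a["chrom"], int(a["start"]), int(a["end"]), a["direction"]),
            int(a["cn"]),
        )
        for a in doc.get("aberrations", [])
    )
    return KaryotypePreset(doc["name"], doc["sex"], abrs)
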