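"""Generative model of single-cell two-channel BAC-array profiles.

A cell in G0/G1 carries its constitutive copy number ``c`` at every locus; a
G2/M cell carries ``2c`` everywhere (which normalization cancels); an S-phase
cell at progression ``s`` has replicated each of its ``c`` copies of a locus
with probability ``p(s, t)`` that rises as ``s`` passes the locus' replication
timing ``t``, so the effective DNA content oscillates between ``c`` and
``2c`` along the genome (copy state 2, 3 or 4 for a diploid locus).  Origin
firing is stochastic but organized: probes of one replication domain share a
domain-level draw, which produces the long runs of jointly elevated or
depressed log2 ratios that defeat a consecutive-probe detection rule.

The test channel is the (amplified) single cell, the reference channel bulk
DNA of the opposite sex: constitutively 2 copies on autosomes and no
replication oscillation, since a bulk extract averages over cell-cycle
phases.  Whole-genome amplification contributes multiplicative log-normal
per-probe bias, hybridization an additional log-scale measurement noise, and
each probe has an affinity shared between the two channels (it cancels in the
ratio but shapes raw intensities).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import binom

from .genome import KaryotypePreset, ProbeMap, TimingTrack

__all__ = [
    "CellState",
    "ReplicationModel",
    "NoiseModel",
    "IntensityTable",
    "CohortDesign",
    "replication_probability",
    "constitutive_copies",
    "simulate_effective_copies",
    "simulate_intensities",
    "simulate_cohort",
    "cell_rng",
]

PHASES = ("G0G1", "S", "G2M")


@dataclass(frozen=True)
class CellState:
    """A single cell: identity, true cell-cycle phase and S-progression."""

    cell_id: str
    phase: str
    karyotype: KaryotypePreset
    s: float | None = None  # S-phase progression fraction, only for phase == "S"

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        if self.phase == "S":
            if self.s is None or not 0 <= self.s <= 1:
                raise ValueError("S-phase cell needs progression s in [0, 1]")
        elif self.s is not None:
            raise ValueError("progression s is defined only for S-phase cells")


@dataclass(frozen=True)
class ReplicationModel:
    """Stochastic origin-firing model.

    ``tau`` sets how sharply a locus' replication is concentrated around its
    timing ``t``: the probability that a locus with timing ``t`` has been
    replicated by progression ``s`` is ``logistic((s - t)/tau)``, 0.5 exactly
    at ``s == t`` and a step function as ``tau -> 0``.  ``domain_weight`` is
    the share of firing variance common to all probes of one replication
    domain (a Gaussian-copula mixing weight).
    """

    tau: float = 0.1
    domain_weight: float = 0.7

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if not 0 <= self.domain_weight <= 1:
            raise ValueError("domain_weight must be in [0, 1]")


def replication_probability(s, t, model: ReplicationModel | None = None):
    """Probability that a locus with timing ``t`` is replicated at progression ``s``."""
    model = model or ReplicationModel()
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any((s < 0) | (s > 1)) or np.any((t < 0) | (t > 1)):
        raise ValueError("s and t must lie in [0, 1]")
    p = expit((s - t) / model.tau)
    return float(p) if p.ndim == 0 else p


@dataclass(frozen=True)
class NoiseModel:
    """WGA and hybridization noise in log2 units, plus per-probe SNR simulation.

    Defaults are calibrated so that noiseless expectations dominate:
    amplification bias sd 0.25, hybridization noise sd 0.15, probe affinity sd
    0.5 (all log2).  Intensities are in units of the one-copy signal at median
    affinity; ``background`` is the additive non-specific floor.  Its default
    of one copy-equivalent models the high background of amplified single-cell
    material and compresses observed log2 ratios to the amplitudes single-cell
    BAC arrays actually show (a 3:2 gain reads near +0.4, not +0.58), which is
    why the +/-0.3 calling threshold is genuinely marginal.  SNR is
    log-normal; with median 10 and log-sd 1 roughly 5% of probes fall under
    the conventional exclusion threshold of 2.
    """

    sigma_wga: float = 0.25
    sigma_hyb: float = 0.15
    affinity_sd: float = 0.5
    background: float = 1.0
    snr_median: float = 10.0
    snr_log_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sigma_wga", "sigma_hyb", "affinity_sd", "background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


NOISELESS = NoiseModel(sigma_wga=0.0, sigma_hyb=0.0, affinity_sd=0.0,
                       background=0.0, snr_log_sd=0.0)


@dataclass
class IntensityTable:
    """Two-channel intensities per probe for one cell, plus its metadata."""

    data: pd.DataFrame  # columns: probe_id, test, ref, snr
    cell: CellState

    def __post_init__(self) -> None:
        need = {"probe_id", "test", "ref", "snr"}
        if not need <= set(self.data.columns):
            raise ValueError(f"intensity table needs columns {sorted(need)}")


def constitutive_copies(karyotype: KaryotypePreset, probe_map: ProbeMap) -> np.ndarray:
    """Constitutive copy number per probe: 2 on autosomes, sex-dependent on X/Y."""
    c = np.full(len(probe_map), 2, dtype=np.int64)
    chrom = probe_map.df["chrom"].values
    if karyotype.sex == "XY":
        c[np.isin(chrom, ["chrX", "X", "chrY", "Y"])] = 1
    else:
        c[np.isin(chrom, ["chrY", "Y"])] = 0
    for ab in karyotype.aberrations:
        c[probe_map.region_mask(ab.region)] = ab.cn
    return c


def _reference_copies(cell_sex: str, probe_map: ProbeMap) -> np.ndarray:
    """Reference channel: bulk diploid DNA of the opposite sex."""
    ref_sex = "XY" if cell_sex == "XX" else "XX"
    return constitutive_copies(
        KaryotypePreset("reference", ref_sex, ()), probe_map
    )


def simulate_effective_copies(
    cell: CellState,
    probe_map: ProbeMap,
    track: TimingTrack,
    model: ReplicationModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-probe effective DNA copies of one cell.

    G0/G1 returns the constitutive copies exactly and G2/M twice that.  In S
    phase each probe adds ``Binomial(c, p(s, t))`` replicated copies, with the
    binomial uniform driven by a Gaussian copula mixing a domain-level draw
    (weight ``model.domain_weight``) with probe-level jitter, so probes of one
    replication domain fire together more often than not.
    """
    c = constitutive_copies(cell.karyotype, probe_map)
    if cell.phase == "G0G1":
        return c
    if cell.phase == "G2M":
        return 2 * c
    p = replication_probability(cell.s, track.timing, model)
    w = model.domain_weight
    dom = track.domain_id
    uniq, inv = np.unique(dom, return_inverse=True)
    z_dom = rng.standard_normal(uniq.size)[inv]
    z_probe = rng.standard_normal(len(c))
    u = _norm_cdf(np.sqrt(w) * z_dom + np.sqrt(1 - w) * z_probe)
    replicated = binom.ppf(u, c, p).astype(np.int64)
    return c + replicated


def _norm_cdf(z: np.ndarray) -> np.ndarray:
    from scipy.special import ndtr

    # keep the copula uniform strictly inside (0, 1) for binom.ppf
    return np.clip(ndtr(z), 1e-12, 1 - 1e-12)


def simulate_intensities(
    copies: np.ndarray,
    probe_map: ProbeMap,
    cell: CellState,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> IntensityTable:
    """Two-channel intensities for given per-probe effective copies.

    ``test = affinity * copies * 2^eps_test + background`` and
    ``ref = affinity * ref_copies * 2^eps_ref + background`` with independent
    per-channel WGA and hybridization log2 noise; the probe affinity is shared
    between channels and cancels in the ratio.
    """
    n = len(probe_map)
    copies = np.asarray(copies, dtype=float)
    if copies.shape != (n,):
        raise ValueError("copies must align with the probe map")
    affinity = 2.0 ** rng.normal(0.0, noise.affinity_sd, size=n)
    eps_test = rng.normal(0.0, noise.sigma_wga, n) + rng.normal(0.0, noise.sigma_hyb, n)
    eps_ref = rng.normal(0.0, noise.sigma_wga, n) + rng.normal(0.0, noise.sigma_hyb, n)
    ref_copies = _reference_copies(cell.karyotype.sex, probe_map)
    test = affinity * copies * 2.0**eps_test + noise.background
    ref = affinity * ref_copies * 2.0**eps_ref + noise.background
    if noise.snr_log_sd > 0:
        snr = noise.snr_median * np.exp(rng.normal(0.0, noise.snr_log_sd, n))
    else:
        snr = np.full(n, noise.snr_median)
    data = pd.DataFrame(
        {"probe_id": probe_map.df["probe_id"].values, "test": test, "ref": ref,
         "snr": snr}
    )
    return IntensityTable(data=data, cell=cell)


@dataclass
class CohortDesign:
    """Study design for one simulated cohort.

    Defaults mirror the study conditions: cells drawn per phase from one
    karyotype, S-progressions uniform on [0.1, 0.9] (FACS gates exclude the
    extremes of S), and an optional phase mislabel rate mimicking sorting
    impurity.
    """

    counts: dict[str, int]
    karyotype: KaryotypePreset
    replication: ReplicationModel = field(default_factory=ReplicationModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    s_range: tuple[float, float] = (0.1, 0.9)
    mislabel_rate: float = 0.0

    def __post_init__(self) -> None:
        bad = set(self.counts) - set(PHASES)
        if bad:
            raise ValueError(f"unknown phases in design: {sorted(bad)}")
        if not 0 <= self.mislabel_rate <= 1:
            raise ValueError("mislabel_rate must be in [0, 1]")


def cell_rng(seed: int, cell_id: str) -> np.random.Generator:
    """Per-cell substream: global seed + stable hash of the cell id.

    Changing cohort membership therefore never perturbs other cells' draws.
    """
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(cell_id.encode())])


def simulate_cohort(
    design: CohortDesign,
    probe_map: ProbeMap,
    track: TimingTrack,
    seed: int,
) -> list[tuple[CellState, IntensityTable]]:
    """Simulate a cohort of single cells; reproducible given ``seed``.

    Returns one ``(CellState, IntensityTable)`` pair per cell with unique
    cell ids ``{karyotype}_{phase}_{i}``.  The recorded phase label can be
    wrong with probability ``mislabel_rate`` (the cell is simulated from a
    different true phase than its label, as an impure sort would produce);
    the returned ``CellState`` carries the *true* phase.
    """
    out: list[tuple[CellState, IntensityTable]] = []
    lo, hi = design.s_range
    for phase in PHASES:
        n = design.counts.get(phase, 0)
        for i in range(1, n + 1):
            cell_id = f"{design.karyotype.name}_{phase}_{i}"
            rng = cell_rng(seed, cell_id)
            true_phase = phase
            if design.mislabel_rate > 0 and rng.random() < design.mislabel_rate:
                true_phase = "G0G1" if phase == "S" else "S"
            s = float(rng.uniform(lo, hi)) if true_phase == "S" else None
            cell = CellState(cell_id, true_phase, design.karyotype, s)
            copies = simulate_effective_copies(
                cell, probe_map, track, design.replication, rng
            )
            table = simulate_intensities(copies, probe_map, cell, design.noise, rng)
            out.append((cell, table))
    return out
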