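import numpy as np
import pytest

import sphasecgh as sc


@pytest.fixture(scope="session")
def study_map():
    """The study-matched probe map with its default timing track attached."""
    return sc.study_probe_map()


@pytest.fixture(scope="session")
def study_track(study_map):
    return sc.generate_timing_track(study_map, seed=101)


@pytest.fixture(scope="session")
def tracked_map(study_map, study_track):
    return study_map.with_timing(study_track)


@pytest.fixture(scope="session")
def presets():
    return sc.study_presets()


@pytest.fixture(scope="session")
def diploid_xx():
    return sc.KaryotypePreset("diploid", "XX", ())


@pytest.fixture(scope="session")
def small_map():
    """A 500-probe autosome-only map for fast synthetic constructions."""
    cfg = sc.MapConfig(
        chrom_lengths={"chr1": 120_000_000, "chr2": 100_000_000}, n_probes=500
    )
    return sc.generate_probe_map(cfg, seed=3)


def make_profile(
    karyotype,
    probe_map,
    track,
    phase="G0G1",
    s=None,
    noise=None,
    seed=0,
    tau=0.1,
    domain_weight=0.7,
):
    """Simulate one cell end to end and return its normalized profile."""
    noise = noise if noise is not None else sc.NOISELESS
    cell = sc.CellState(f"{karyotype.name}_{phase}", phase, karyotype, s)
    rng = np.random.default_rng(seed)
    model = sc.ReplicationModel(tau=tau, domain_weight=domain_weight)
    copies = sc.simulate_effective_copies(cell, probe_map, track, model, rng)
    table = sc.simulate_intensities(copies, probe_map, cell, noise, rng)
    return sc.preprocess(table, probe_map)
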