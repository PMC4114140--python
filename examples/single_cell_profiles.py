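"""Simulate one S-phase and one G0/G1 cell of a duplication carrier.

Builds the matched probe map, simulates the two cells under default
amplification/hybridization noise, normalizes their two-channel intensities
and applies the detection rule to the 25.16 Mb duplication, then prints the
oscillation statistics used for phase attribution.
"""

import numpy as np

import sphasecgh as sc

pm = sc.study_probe_map()
track = sc.generate_timing_track(pm, seed=11)
pm = pm.with_timing(track)
preset = sc.study_presets()[0]  # 25.16 Mb duplication carrier
region = preset.aberrations[0].region
model, noise = sc.ReplicationModel(), sc.NoiseModel()

for phase, s, seed in (("S", 0.4, 5), ("G0G1", None, 6)):
    cell = sc.CellState(f"demo_{phase}", phase, preset, s)
    rng = np.random.default_rng(seed)
    copies = sc.simulate_effective_copies(cell, pm, track, model, rng)
    table = sc.simulate_intensities(copies, pm, cell, noise, rng)
    profile = sc.preprocess(table, pm)
    call = sc.evaluate_region(profile, region, sc.DetectionConfig())
    stats = sc.classify_phase(sc.early_late_statistics(profile, track))
    print(f"{phase:5s} cell: {call.k}/{call.n} probes support the gain "
          f"(longest run {call.longest_run}) -> {call.klass}")
    print(f"      oscillation: early-late = "
          f"{stats.early_mean - stats.late_mean:+.3f} log2, "
          f"r_t = {stats.r_t:+.2f}, call = {stats.call}")

print()
print("The S cell, caught mid-replication, supports the duplication with")
print("fewer probes (often under the at-least-half rule: an underestimated")
print("or missed imbalance), while its genome-wide early/late oscillation")
print("betrays its phase; the G0/G1 cell shows neither.")
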