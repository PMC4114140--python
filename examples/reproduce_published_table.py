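"""Reproduce the per-phase false-negative summary from the packaged counts.

The package ships the per-cell table of how many BAC probes passed the
+/-0.3 log2-ratio threshold in each region of interest for 26 S-phase and
22 G0/G1-phase single cells of three carrier cell lines.  Applying the
at-least-half detection rule per region and aggregating per cell gives the
per-phase summary, the chi-square comparison of detection accuracy between
phases, and the rank-sum comparisons of the probe fractions.
"""

import sphasecgh as sc

report = sc.format_table1_report()
print(report)
print("Reading: 17 of 26 S-phase cells are false negatives (14 underestimated")
print("imbalances, 3 outright no-calls) against 4 of 22 in G0/G1; the")
print("chi-square p of 0.001 says detection accuracy depends on cell-cycle")
print("phase, and the rank-sum p-values compare the per-region fractions of")
print("probes supporting the imbalance (significant only for regions > 9 Mb).")
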