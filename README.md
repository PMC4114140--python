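# sphasecgh

Cell-cycle-aware simulation and calling of segmental chromosome imbalances
in single-cell BAC-array CGH.

## The problem

In preimplantation genetic diagnosis (PGD) for balanced-translocation
carriers, single blastomeres are profiled by two-channel BAC-array CGH and
an unbalanced embryo is recognized from segmental gains and losses.  A
single cell caught in S phase, however, has replicated only part of its
genome: stochastic origin firing organized in early/late replication
domains leaves each locus with 1x or 2x of its constitutive copy number, so
the log2 intensity ratios oscillate along the genome.  That oscillation can
dilute the evidence for a real duplication or deletion below the calling
threshold — a false negative with direct clinical consequences.

This package provides, for S and G0/G1 single cells:

- a **probe/genome model** (`sphasecgh.genome`): 24sure-like BAC probe maps
  with subtelomeric/pericentromeric enrichment, GC content, replication
  timing tracks with domain structure, and the three carrier-cell-line
  karyotypes of the reference study (a 25.16 Mb dup(7p); a 24 Mb dup(9p)
  with an 8 Mb del(18p); a 9.3 Mb dup(18p) with a 1.7 Mb del(20p));
- a **generative model** (`sphasecgh.simulate`): per-locus replication state
  from a logistic origin-firing model `p(s, t) = logistic((s - t)/tau)` with
  domain-shared draws, and two-channel intensities under whole-genome
  amplification bias, hybridization noise, shared probe affinities and an
  additive background floor;
- **preprocessing** (`sphasecgh.preprocess`): signal-to-noise filtering
  (exclude SNR < 2) and ratio-of-means normalization to log2 ratios;
- the **detection rule** (`sphasecgh.detect`): a probe calls a gain/loss
  beyond +/-0.3 log2; a region is accurately detected when at least half of
  its probes agree, reliably when additionally 10 consecutive probes do;
  per-cell classification into accurate / underestimated / no-call;
- **phase attribution** (`sphasecgh.phase`): early-vs-late rank-sum test,
  Spearman correlation with replication timing and a GC-trend slope decide
  S-like vs G-like;
- **statistics** (`sphasecgh.stats`): Mann-Whitney U (mid-rank ties,
  exact enumeration for small samples, Edgeworth-refined normal
  approximation otherwise) and Pearson chi-square on 2x2 tables, plus the
  packaged per-cell probe-count table of the reference study (26 S and 22
  G0/G1 cells) and the builders of its per-phase summary.

## Worked example

```
$ python examples/reproduce_published_table.py
Per-phase detection summary (from packaged per-cell counts)

phase    underest.  no call  false neg.  total
S               14        3          17     26
G0G1             3        1           4     22

Mann-Whitney, all regions (fractions): p = 0.330
Mann-Whitney, regions > 9 Mb:          p = 0.024
Chi-square, accurate vs FN by phase:   p = 0.001
```

Seventeen of 26 S-phase cells fail to show at least one of their known
imbalances over at least half of the region's probes (14 underestimations,
3 complete no-calls), against 4 of 22 G0/G1 cells; the chi-square test says
the detection accuracy depends on cell-cycle phase.  The rank-sum tests
compare, between phases, the per-(cell, region) fractions of probes
supporting the imbalance: the deficit is significant for the regions larger
than 9 Mb and not genome-wide.

The same contrast emerges from the simulator alone
(`examples/detection_deficit_study.py`, 25 cells per phase):

```
        cell_line region  size_mb  rate_G0G1  rate_S  gap
       dup7p_line  dup7p    25.16       1.00    0.76 0.24
 der18_t9_18_line  dup9p    24.00       1.00    0.12 0.88
der20_t18_20_line dup18p     9.30       0.92    0.16 0.76
 der18_t9_18_line del18p     8.00       1.00    1.00 0.00
der20_t18_20_line del20p     1.70       1.00    0.96 0.04
```

Duplications lose tens of points of sensitivity in S phase; deletions stay
detectable because even a fully replicated one-copy segment remains well
below the genome average.  `examples/single_cell_profiles.py` and
`examples/phase_classification.py` walk through one cell and one cohort.

A thin CLI wraps the same pipeline: `sphasecgh simulate`, `sphasecgh
analyze`, `sphasecgh reproduce-table1`, `sphasecgh report`.

## Layout

```
src/sphasecgh/       library (genome, simulate, preprocess, phase, detect,
                     stats, study, pipeline, cli; data/table1a.tsv fixture)
examples/            narrative scripts, one per capability
tests/               pytest suite (unit, property and acceptance tests)
scripts/acceptance.py
docs/methods.md      modelling and design notes
```
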