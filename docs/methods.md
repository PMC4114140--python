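# Methods

## Coordinate system and probe maps

All analysis is expressed per probe of an ordered BAC map.  Coordinates are
1-based closed intervals (the cytogenetics convention); a probe belongs to a
region iff its interval midpoint lies inside the region, so a ~150 kb clone
straddling a boundary is never counted twice.  Synthetic maps place probe
midpoints at jittered quantiles of a piecewise-constant density with weight
`enrichment` (default 2) on the terminal 10% of each chromosome, mimicking
the subtelomeric/pericentromeric enrichment of PGD arrays; probe extents are
clipped to guarantee non-overlap.  GC content follows an AR(1) process along
each chromosome (mean 0.41, sd 0.05, correlation length 2 Mb).

The matched map reproduces the five published region probe totals (40, 42,
28, 30, 8) by replacing the generated probes inside each study window with
the exact number, evenly spaced.  The windows' GC is drawn from the AT-rich
end of the distribution (mean 0.36, sd 0.03): the study regions lie in
gene-poor p-arm bands, and through the GC-timing coupling this makes them
lean late-replicating — which is the property that exposes them to S-phase
masking.  The true clone coordinates of the commercial array are
proprietary; everything about the map other than the five probe totals and
the region sizes is synthetic.

## Replication timing

Timing `t` is per probe in [0, 1] (0 = replicates first).  Chromosomes are
segmented into domains with exponential lengths (mean 1 Mb, clipped to
[0.2, 5] Mb).  A domain's timing is `Phi(-w)` with
`w = rho * z_gc + sqrt(1 - rho^2) * eps`, where `z_gc` is the standardized
mean GC of the domain's probes and `eps` a standard normal draw, so GC-rich
domains replicate early (default coupling `rho = 0.6`; the realized
probe-level correlation is attenuated a few points by the probit transform
and within-domain GC spread).  Probe-level jitter is uniform on
`+/-1.5 * jitter_sd` (default sd 0.02), so two probes of one domain differ by
at most `3 * jitter_sd` deterministically.  A domain is early iff `t < 0.5`.
Timing is cell-type specific in reality; the in-silico study therefore
draws an independent track per cell line.

## Generative model of a single-cell hybridization

A G0/G1 cell carries its constitutive copy number `c` everywhere (2 on
autosomes, aberration intervals at 1 or 3, X/Y by sex); a G2/M cell carries
`2c`, which normalization cancels.  An S-phase cell at progression
`s ~ U(0.1, 0.9)` has replicated each of the `c` copies of a locus with
probability

    p(s, t) = logistic((s - t) / tau),      tau = 0.1 by default,

equal to 1/2 exactly when `s = t` and a step function as `tau -> 0`; the
effective copies are `c + Binomial(c, p)`.  The binomial uniforms come from
a Gaussian copula mixing one domain-level draw with probe-level noise
(weight 0.7 on the domain), so whole domains fire together and produce the
long runs of jointly elevated/depressed ratios that defeat a
consecutive-probe rule.  `tau = 0.1` spreads a locus' replication over
roughly +/-20% of S phase around its timing.

Channel intensities (test = the cell, reference = bulk DNA of the opposite
sex, constitutively 2 on autosomes and free of replication oscillation,
since a bulk extract averages over phases) are

    test = a * copies * 2^eps_t + b,    ref = a * 2 * 2^eps_r + b,

with a shared probe affinity `a = 2^N(0, 0.5)`, independent per-channel
amplification and hybridization noise `eps = N(0, 0.25) + N(0, 0.15)` (log2
units), and an additive background floor `b`.  Intensities are in units of
the one-copy signal at median affinity; `b = 1` by default.  The floor is
what calibrates the simulated amplitudes to single-cell BAC-array reality:
it compresses a 3:2 gain from +0.58 toward +0.4 (probe-dependently — low
affinity probes compress most), which is why a +/-0.3 threshold is genuinely
marginal and why even G0/G1 cells support an imbalance with only 50-85% of
the region's probes.  Per-probe SNR is log-normal (median 10, log-sd 1),
putting ~5% of probes under the conventional exclusion threshold of 2.
Setting every noise parameter to zero (`NOISELESS`) recovers the analytic
expectations used by the closed-form tests.

Each cell draws from its own random substream (global seed combined with a
CRC of the cell id), so changing cohort membership never perturbs other
cells.

## Preprocessing

Probes with SNR strictly below 2 are excluded (equality retained).  Ratios
are normalized so the ratio of channel means equals 1:
`L = log2(test/ref) - log2(mean(test)/mean(ref))`.  The means are computed
over autosomes only, because the sex-mismatch design would otherwise bias
the scale; this normalization fixes the ratio of means, not the mean of the
per-probe ratios.  Zero-signal probes on X/Y (structural in a sex-mismatch
design) are excluded with a reason rather than treated as errors;
non-positive autosomal intensities are errors naming the probe.  No GC-wave
or replication-domain correction is applied by default — such corrections
have not been shown to recover the S-phase losses — but a hook exists.

## Detection rule

Per probe: gain iff `L > +0.3`, loss iff `L < -0.3` (strict by default;
configurable, and no packaged count depends on the boundary case).  Per
region: `accurate` iff `k >= ceil(n/2)` probes agree with the expected
direction ("at least half", inclusive — e.g. 21/42 counts); *reliable*
additionally requires `min(10, n)` consecutive agreeing probes, so an
8-probe region can be called but carries a below-resolution flag.  `nocall`
iff `k <= floor(n/4)` (configurable); between the two, `underestimated`.
The published per-cell no-call marks are not a deterministic function of
(k, n); when reproducing the packaged table the shipped flags override the
count rule, while simulations use the rule.  Per cell: false negative iff
any constitutive region is not accurate; a no-call anywhere dominates the
subtype.

## Statistics

`rank_sum_test` implements the two-sided Mann-Whitney U with mid-rank ties.
Combined samples of at most 12 observations are tested by exact enumeration
of all group assignments.  Larger samples use the normal approximation with
tie-corrected variance, a 0.5 continuity correction and an Edgeworth term
for the (platykurtic) exact kurtosis of the null U distribution,
`g2 = -6(n1^2 + n2^2 + n1 n2 + n1 + n2) / (5 n1 n2 (N+1))`; this keeps the
approximation within a few 1e-3 of the exact tail down to five observations
per group (verified against a permutation oracle).  The refinement assumes
light ties and decays as 1/n.  The phase comparison pools per-(cell,
region) *fractions* `k/n` — regions differ in probe totals, so raw counts
are not comparable across regions (a count mode exists behind a flag).  The
accuracy comparison is a Pearson chi-square on the 2x2 accurate/false-
negative by phase table, df 1, without Yates correction (with correction
the packaged table's p no longer prints as 0.001).

Applied to the packaged counts these choices give p = 0.330 (all regions),
p = 0.024 (regions > 9 Mb) and chi-square p = 0.001.  The first two were
published as 0.371 and 0.029; no Mann-Whitney variant we tried reproduces
those digits exactly from the printed per-cell counts (the conclusions —
non-significant overall, significant for large regions — are identical).
The packaged table also carries two flag columns: the printed no-call marks
(five S entries) and the subset consistent with the published per-phase
totals and narrative (three S cells, one G0/G1 cell); summary derivation
uses the latter.

## Phase attribution

Autosomal log2 ratios are pooled by early vs late domain (at least 20
probes each, else indeterminate) and compared by the rank-sum test; `r_t`
is the Spearman correlation of `L` with `-t`; the GC slope is a linear fit
of `L` on GC (a linear slope rather than a Loess fit, since the trend is
used as a decision statistic, not for display).  S-like iff `p < 0.01`,
`r_t > 0.2` and early mean above late mean; G-like iff `p >= 0.01` and
`|r_t| <= 0.2`; anything else — including a significant wave in the wrong
direction — is indeterminate.  No published numeric thresholds exist for
this attribution; the defaults are package choices.  G2/M cells are
indistinguishable from G0/G1 here (uniform doubling normalizes away), so
concordance pools them as "G".  Degenerate profiles (constant ratios) give
p = 1, r = 0.

## In-silico study and what it shows

`study.detection_rate_study` re-creates the study design: the matched map,
an independent timing track per cell line, 100 S + 100 G0/G1 cells per line
under default models, full pipeline, per-region accurate-detection rates.
Under these conditions duplications lose large double-digit percentages of
sensitivity in S phase (the acceptance run at seed 1 measures gaps of 50,
43 and 23 points for the 25.16, 24 and 9.3 Mb duplications), while
deletions are essentially unaffected: even a fully replicated one-copy
segment reads `(1+p)/(1+pbar) <= 2` of a two-copy locus and stays below the
-0.3 threshold except in a narrow early-S corner.  The published per-cell
counts show the same asymmetry (the 8 Mb deletion's accurate-rate gap is
7.5 points, versus 66-69 points for the 25.16 and 9.3 Mb duplications), so
the simulator reproduces the qualitative phenomenon and its structure, not
a uniform per-region deficit.  `study.concordance_study` (50+50 cells)
classifies phase with ~99% concordance; the analogous published figure is
44 of 48 cells, on real data whose amplification failures the simulator
does not model.

Problem sizes used by the default test run and the acceptance script (3000
probes, 100+100 cells per line for detection, 50+50 for concordance) are
the package's reference study conditions; rates stabilize to within a few
points at these sizes.

## What the generator does not model

Allele dropout and WGA chimeras; per-cell amplification-quality variation
(every simulated cell shares one noise level, so the catastrophic
single-cell failures seen on real arrays have no counterpart); FACS gating
(phase labels are exact unless a mislabel rate is set); real clone
coordinates and real replication-ratio tracks (synthetic timing tracks
stand in; the phase-attribution API accepts any track so a measured one can
be substituted).  Passing tests therefore demonstrate the mechanism and the
pipeline's correctness on the modelled physics, not calibrated performance
on any real array platform.
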