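# Methods

This note documents the statistical procedures `boltchip` implements, the
defaults it ships, the design choices made where the underlying analysis
recipe left the details open, and what the synthetic-data tests do and do not
demonstrate.

## Study design being modelled

Six biennial sugar beet genotypes — three bolting-resistant (R1–R3), three
bolting-sensitive (S1–S3) — are profiled after nine weeks of vernalization.
Each genotype contributes one one-colour expression array (Cy3-labelled cRNA)
and one two-colour MeDIP array (anti-5-methylcytosine immunoprecipitate in
Cy5 against input DNA in Cy3). Because one immunoprecipitation is performed
per genotype, the biological replicates of each condition are the three
genotypes of the tolerance group; all between-group tests in this package are
3-vs-3 comparisons across genotypes, and this is the dominant limit on power.

## Cot design math

The single-copy Cot1/2 of a genome is estimated by scaling the *E. coli*
standard with the genome-size ratio, `y = Cot1/2_coli * G_org / G_coli`
(units M s). With the shipped constants (4.545455 M s, 4.639 Mbp, 1.223 Gbp)
the raw estimate is 1198.3 M s; the package reports both the raw value and
the two-significant-figure value 1200 M s, because the rounded number is what
the design convention uses downstream (the two-decade window of 1200 is
(120, 12 000) M s, within which ~80% of the single-copy component is expected
to reassociate).

## Probe design

Probes are 60-mers on 0-based, half-open coordinates (BED convention).
Tiling anchors at position 0 with a fixed start-to-start spacing and drops
any terminal partial probe, so a source of length L yields
`floor((L - 60)/spacing) + 1` probes; anchoring and end handling are not
prescribed by the original design software (a proprietary tool), and this
closed form is our choice. It reproduces the published organelle design count
(3688 probes on the 368 799 bp mitochondrial genome at 100 bp spacing)
exactly. Expression designs place one probe per transcript at the 5' end; the
"second probe for indistinguishable transcripts" situation is modelled as an
input ambiguity flag per source rather than by re-implementing a sequence
uniqueness screen, and the second probe is placed at the last valid start to
maximize separation. Probe sequence content is taken verbatim from the
source; no melting-temperature, repeat, or cross-hybridization screening is
attempted. Reproducibility controls are 50 distinct control probes, each
replicated 10 times.

## One-colour expression processing

A feature is "well above background" when `bg_sub_signal > 2.6 * bg_sd`
(strict inequality; missing values fail). A probe passes filtering when it
passes all flags (above background, not saturated, not a non-uniformity
outlier) in **every** replicate of at least one condition. Normalization is
per chip to the 75th percentile, per probe to the median across chips, then
log2. The order chip-scaling → probe-centering → log is recorded in the
provenance; since all three steps commute on the log scale up to the constant
factors recorded, the choice only affects provenance bookkeeping, not the
test statistics. Consequences asserted in tests: the normalized matrix is
invariant to rescaling any chip by a positive constant, and the per-probe
linear-scale median is 1.

DEG calling: fold change is the geometric-mean ratio `2**|mean_S - mean_R|`
of log2 values, thresholded inclusively at 2; the test is a pooled-variance
two-sample t-test (the default of the MeV-style analysis this emulates), with
Welch available via `equal_var=False`. Significance requires both the fold
change gate and a p-value below alpha = 0.05 — Benjamini–Hochberg adjusted by
default, with `adjust="none"` available because the original accounting used
raw p for its table-level counts. Degenerate rows (zero variance in both
groups) get p = 1 when the means agree and p = 0 when they differ, rather
than an exception.

## Two-colour MeDIP processing

Per sample, the quality set for normalization contains probes that are above
background in both channels (2.6 × SD rule per channel), unsaturated,
non-outlier, and whose within-sample intensity ranks agree between the dyes
to within `rank_tolerance * N` (default 0.05, a chosen default — the vendor's
"similar ranks" criterion is not quantified publicly). The linear dye
correction multiplies Cy5 by `mean(Cy3)/mean(Cy5)` over the quality set, so
the channel means agree exactly on that set, then reports
`log2(scale * Cy5 / Cy3)` per probe. Positive ratios mean methylation
enrichment (input Cy3 is the denominator). DMRs are called on the ratio
matrix with the same differential core as expression, at two tiers: raw
p < 0.01 (primary, reported as `significant`) and p < 0.05 (screen). Raw
rather than adjusted p is the default here because the multiple-testing
correction was described only for the transcriptomic arm; BH is available by
flag.

A consequence worth knowing: because the linear normalization equalizes
channel means per array, a methylation offset shared by *all* probes of an
array is absorbed into the scale factor. Organelle probes are therefore
processed as part of the whole-array table (they are a small minority of it)
and the ratio matrix is restricted to them afterwards; normalizing an
organelle-only table would delete the genome-wide group offset by
construction.

## Integration

DEMSs are the set intersection of significant DEG and DMR sequence ids
(symmetric, deterministic order). Methylation–expression correlation is
Pearson on raw pairs and Spearman on average ranks, by default over
per-genotype pairs (six per sequence), with a group-mean mode (two per
sequence) for printed summary tables. The packaged joint-call table of 14
accessions gives, in group-mean mode over its 28 pairs, Pearson r = −0.350
and Spearman ρ = −0.340 (frozen from an independent from-scratch computation;
the original per-genotype analysis reported r = −0.34, which is not asserted
because the per-genotype values are not printed). Cross-platform fold-change
agreement is Pearson on log2 fold changes of the shared genes.

The organelle track is the per-probe R and S group mean log ratio at each
probe start, unsmoothed. The genome is partitioned by the annotation into
coding (merged ORF/tRNA/rRNA intervals; a probe is coding when its interval
overlaps the union) and non-coding (the complement), with CpG islands kept as
a separate layer. The R-vs-S contrast is a paired two-sided t-test across
probes on the per-probe group means — paired because the same probes are
measured in both groups; the original report does not name its test. The
coding-vs-non-coding contrast is a two-sample t-test on per-probe overall
means grouped by region. Probes are treated as spatially independent in both
tests; no autocorrelation correction is applied, which anti-conservatively
inflates significance on smooth tracks — a documented limitation. DMR-rich
loci are found by 1-D single-linkage clustering of significant probe
positions: gaps ≤ 5 kb join a locus, loci need ≥ 3 probes (both invented
defaults calibrated so that 10–15 kb planted loci are reported as such;
both exposed in configuration).

## Phenotype and genetics

Bolting index is `100 * bolted / n` at a cold duration (censored plants stay
in the denominator); bolting delay averages day-of-bolting over bolted plants
only (the censoring convention is ours) and is an error, not zero, when
nothing bolted. Tolerance classes use the final-duration BI: sensitive at
≥ 75%, resistant at ≤ 20%, intermediate otherwise — thresholds anchored to
the observed extremes (sensitive lines reached 75–100%; the weakest resistant
response was 15%) and configurable. SNP clustering uses 1 − IBS distance over
pairwise-complete markers and average linkage; the variance summary is the
fraction of variance on the first two principal coordinates, reported but
never thresholded, because the method behind the original "~46% of variance"
figure is unknown.

## Synthetic data

The generators reproduce the structure of the study, not its biology:

* expression: per-probe baseline log2 signal ~ N(8, 1.5); 169 planted DEGs
  (82 up-in-S, 87 up-in-R) shifted by 1.6 log2 units (≈ 3-fold) in the
  designated group; measurement noise N(0, 0.2) on the log2 scale;
* methylation: true log ratios 0, 111 planted DMRs at +1.5 in S, per-sample
  Cy5 dye bias drawn in [1/1.5, 1.5], per-channel QC columns; 14 of the DMRs
  coincide with planted DEGs (the DEMS set);
* organelle: a random genome (368 799 bp by default), packed ORF/tRNA/rRNA
  and CpG-island intervals, probes at 100 bp; baseline ratio −0.5 (organelle
  methylation reads low), +0.3 in R genome-wide, +0.4 in non-coding, and two
  windows of 12.0 and 14.5 kb with +1.2 extra in R (the DMR-rich loci);
  feature counts and window spans scale proportionally on shorter test
  genomes;
* SNPs: 708 markers, two clusters with Beta(0.5, 0.5) cluster-specific
  allele frequencies, membership drawn independently of the tolerance groups;
* phenotypes: sensitive lines start bolting at 9 weeks and reach ≥ 75% BI
  with 17–55 d delays; resistant lines stay ≤ 20% with ~85 d delays.

The error model (log-normal signals, additive Gaussian log2 noise,
multiplicative dye bias) is a modelling choice; no error model was published.
Two deliberate simplifications keep the ground truth exact: QC failures
(saturation, non-uniformity, below-background) are planted only on
non-planted probes, and planted effects are drawn from the
above-background pool — so in the noiseless limit the pipeline recovers
100% of the truth, and any shortfall under noise is attributable to the
statistics, not to bookkeeping. What passing tests therefore show is that the
processing chain is correct and that the planted effect sizes are detectable
at 3-vs-3; they do not show robustness to real-array artefacts (spatial
gradients, probe-sequence effects, intensity-dependent dye bias, correlated
noise), none of which are simulated.

All randomness derives from a single integer seed through independent named
substreams, so every table is bit-identical across runs and call orders, and
the two array generators agree on the shared (dye bias, planted id) state
without sharing objects.

## Problem sizes and defaults

Desk-scale defaults are 5000 expression and 20 000 methylation probes —
roughly a tenth of the published arrays (53 752 and 227 242, available via
`full_scale()`) — which keeps the full test suite under a minute on one
CPU. The property-based acceptance checks run at 2000 expression probes
(null false-positive control over 100 seeds, and planted-DEG recovery), a
500-probe organelle track for the contrast checks, and the full-length
organelle genome for the locus-span check. Recovery of planted ~3-fold DEGs
at these sizes is ≥ 90% with BH correction; with the raw-p selection rule
that the joint (DEMS) table uses, recovery of the 14 planted joint sequences
is exact. The DEMS acceptance check applies exactly that rule — raw p < 0.05
on the expression side and the fold-change + screen-tier rule on the
methylation side — matching the selection criteria stated for the joint
table rather than the stricter headline DEG/DMR tiers.
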