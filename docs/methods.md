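# Methods

## Data model and conventions

All coordinates are 0-based half-open; a CpG dyad is identified by the
position of its forward-strand C, and 1-based inputs (cytosine reports,
RepeatMasker, TRF) are converted at the parser boundary.  A methylome is a
table of `(chrom, pos, context, meth_reads, total_reads)` with unique
keys; duplicate positions in an input file are an error rather than being
silently summed, which catches accidentally concatenated files.  Reads
from the two strands of a dyad are combined before analysis; total counts
are conserved exactly by the merge, and reverse-strand calls without a
matching dyad are kept as orphans and counted.  Bisulfite sequencing
cannot distinguish 5-methylcytosine from 5-hydroxymethylcytosine, so all
levels are mC+hmC.  Non-CpG contexts (CHG/CHH) pass through parsing and
are summarized only as global per-context means; there is no non-CpG
windowing.

Depth filtering is explicit and separate from parsing: zero-coverage
cytosines survive the parsers and are dropped by `filter_depth`.  The
default thresholds follow the sequencing depth structure of the samples —
≥ 3 reads for oocytes, ≥ 5 for all other samples.  Replicate pooling sums
counts *before* depth filtering, so a position below threshold in every
replicate can still qualify in the pool.  Bisulfite conversion is
estimated from an unmethylated spike-in contig as
`1 − Σmeth/Σtotal` over all cytosine contexts.

## Statistics

Region and window means are **unweighted means of per-CpG levels** (each
CpG contributes its `meth/total` once), not read-count-weighted pooled
ratios; a coverage-weighted variant is available by flag.  A mean is
undefined (NaN, never an exception) below the kind-specific minimum of
covered CpGs: 10 for CGIs and promoters, 5 for repeat copies, 10 of 20
CpGs for windows.

The window change test is the classical equal-variance two-sample
Student's *t* on the per-CpG level vectors of a window in the two samples
(a paired mode restricted to co-covered CpGs exists behind a flag; the
unpaired reading is the default because "Student's t-test" names the
equal-variance unpaired test).  For speed it is computed from per-window
summary statistics (mean, unbiased variance, n) via cumulative sums over
the reference CpG array; this is algebraically identical to the direct
test.  Windows where both groups are constant but unequal get p = 0, the
limit of the t statistic, with a logged flag — this avoids NaN propagation
at saturated (0% or 100%) windows.  Benjamini–Hochberg correction is
applied per pairwise comparison across that comparison's testable windows
only; untestable windows are excluded before correction so they do not
dilute it.

The 2×2 chi-square is the uncorrected Pearson statistic with 1 df by
default (Yates correction by flag); a zero marginal is an error surfaced
cleanly rather than a NaN.  The Mann–Whitney U test uses exact enumeration
for samples of at most 20 without ties and a tie-corrected normal
approximation otherwise; fully tied data (zero rank variance) yields
p = 1.  BH-adjusted q-values dominate their p-values and preserve their
ordering; note that the step-up adjustment is *not* idempotent
(reapplying it can only increase q-values), so no code relies on
reapplication being a no-op.

## The passive-demethylation model

The zygote averages the two parental alleles; each replication-dependent
global demethylation event halves the maternally contributed methylation
while the paternal contribution is held at its input value (its loss is
active, not replication-coupled; a co-dilution flag exists for modelling
both).  Expected level = `100 · (m_mat · 2^-k + m_pat) / 2`.  The
diagnostic bound: a region fully methylated on the maternal allele and
unmethylated on the paternal allele sits at exactly 25% after one event —
so oocyte-specific regions observed well above 25% in blastocysts argue
against a passive genome-wide dilution of the maternal genome.

## Thresholds

All classification cutoffs are configurable; the defaults are: hyper
≥ 80%, hypo ≤ 20% (both inclusive), window change > 20 points with
q < 0.05, the protection screen strictly > 70%, ES-cell loss strictly
> 75%, the blood maintenance interval for germline DMRs [35%, 65%]
closed on both ends, gene-body/expression analysis restricted to genes
> 5 kb, RPKM floored at 0.01 before log2, active/inactive expression
boundary log2(RPKM) = −5 for human (0 for mouse), repeat families ranked
only when they exceed 100 genomic copies.

A classification edge the rule set must decide: a germline DMR whose
blood level falls outside [35, 65] without a placenta-maintained
catalogue flag keeps its germline class (by hyper gamete) so that the
four classes partition all classifiable records; the placenta flag is
catalogue metadata, never inferred, because no placenta methylome enters
the analysis.

## Window geometry

Windows hold exactly 20 reference CpGs and advance by 10, giving
`floor((N−20)/10)+1` windows per chromosome and two covering windows for
every interior CpG.  Windows are anchored on a reference CpG map (all
genomic dyads — in practice the union of positions seen across samples),
not on per-sample covered CpGs, so window identity is comparable across
samples.  Genomic location labels use any-overlap semantics with priority
promoter > exon > intron > intergenic.

## Synthetic data generator

`simulate.build_reference` lays out a few ~2 Mb chromosomes (the last one
an X) as a shuffled sequence of feature cassettes separated by
CpG-sparse background (≈1 CpG/200 bp): CpG-dense islands (1 kb, 8 bp
spacing) with planted gamete categories (20% oocyte-specific, 15%
sperm-specific, 40% both-hyper, 15% both-hypo, 10% intermediate), an
imprinted-DMR catalogue (per autosome: 8 maternal gDMRs of which a third
are planted as ES-hypermethylation losses, 1 paternal gDMR, 3
placenta-specific, 3 secondary), genes with promoters and
expression-coupled body methylation (active bodies 85%, inactive 15% in
oocyte), and four repeat families — a VNTR-bearing SVA-like family
(planted protected), alpha-satellite-like (oocyte-hypermethylated),
Alu-like and L1-like controls, each with > 100 copies.  Planted
probabilities are clean (0.90/0.05 for specific regions, 0.50 for
intermediates); all observation noise comes from read sampling.

Read sampling is Poisson(depth) coverage with Binomial(depth, p)
methylated counts after applying bisulfite non-conversion
(`p_obs = p + (1−p)(1−conversion)`, conversion default 0.995, emulating
the >99% rates of real libraries).  Default depths mirror the relative
depth structure of the study design at desk scale: oocyte 7, sperm and
blastocyst 24, blood and ES 16.  A noise-free mode sets counts to
`round(p·1000)` for exact-recovery tests.  Oocyte non-CpG sites get 5%
methylation (CpA-like signal), other samples 0.5%.

Blastocyst truth is model-derived: maternal contribution = oocyte × 0.85
retention, paternal = sperm × 0.10 except at protected CpGs (germline
DMRs, the SVA-like family, VNTR-bearing islands) where it is × 0.90.
Under `mouse_passive` the maternal factor is additionally halved per
replication round except at gDMRs.  On chrX the maternal contribution is
weighted 0.7 (a pooled blastocyst sample includes male embryos whose X is
maternal), reproducing the higher persistence of X-linked
oocyte-methylated islands.

VNTR-bearing both-hyper islands (30% of them) carry tandem arrays whose
copy number is drawn around 25 for protected islands and around 10 for
unprotected ones, with a common period distribution — so the copy-number
comparison between protected and unprotected arrays is significant while
the period comparison is not, mirroring the biological claim that more
repeats correlate with protection.

What the generator does **not** emulate: real sequence composition and
mappability, per-read errors or PCR duplicates, allele-resolved (SNP
phased) methylation, X-inactivation dynamics, realistic repeat-family
breadth, or biological replicate structure.  Passing recovery tests
demonstrates the pipeline's correctness on its own model classes, not
calibration on real human data; the study's real-data headline numbers
require the original deposited methylomes and are reproduced in output
schema only.

## Recovery experiment design

The window-change recovery experiment plants +50-point shifts on the 20
CpGs of 100 windows (chosen ≥ 3 window indices apart) among 1000 windows
at depth 30.  Because adjacent windows share 10 CpGs, each planted
window's two neighbours are genuinely shifted by +25 points — true
intermediate changes, not false positives — so recovery is scored on the
planted windows versus the null windows that share no CpGs with any
shifted span; half-overlap neighbours are excluded from both sets.

## Problem sizes

The default scenario uses three ~2 Mb chromosomes (~24,000 CpGs each,
~7,200 windows, 180 CGIs, 33 catalogue DMRs, ~690 repeat copies, 75
genes), chosen so a full synthetic end-to-end run completes in seconds
while every analysis stage still has enough features for stable medians
and contingency tables.

## Known limitations

- The naive tandem-repeat detector handles exact arrays only (score =
  2 × matched bases, period ≤ 500, score ≥ 150); diverged real VNTRs
  should come from parsed Tandem Repeats Finder output, which feeds the
  same record type.
- Promoters extending past a contig start are clipped at 0 rather than
  dropped.
- The gDMR/CGI VNTR-enrichment chi-square in the small default scenario
  has limited power (16 maternal gDMRs); the statistical machinery is
  exercised at catalogue scale in the test suite instead.
- No plotting layer: all outputs are TSV/BED/JSON for external
  visualization.
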