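# Methods

This note documents the models, thresholds and design choices behind
`monotert`: what each stage computes, what the synthetic cohorts emulate,
and where the package made a judgement call that a maintainer should know
about.

## Data model and coordinates

All genomic positions are 1-based hg19; intervals are closed on both ends.
*TERT* is a minus-strand gene with its translational start (ATG) at
chr5:1,295,104, so its promoter and upstream region lie at *increasing*
coordinates: the canonical hotspots C228T and C250T at chr5:1,295,228 and
1,295,250 are 124 and 146 bp upstream of the ATG. Hotspot substitutions are
stored exactly as written on the plus strand (the C228T/C250T labels are the
interface); the package never rewrites alleles to the opposite strand.

The default hotspot catalog holds six substitutions at five positions —
1,295,191 (A>C), 1,295,228 (C>T and C>A), 1,295,242 (C>T), 1,295,243 (C>T)
and 1,295,250 (C>T). **Known discrepancy:** descriptions of the rare
upstream hotspot disagree between 1,295,161A>C and 1,295,191; the default
catalog uses 1,295,191, and since no reference/alternate pair is documented
for that coordinate it carries the A>C substitution of the rare hotspot
(label `A191C`). The catalog is an input everywhere it is consumed, so
users can substitute their own entries.

## Eligibility filters (anchor selection)

A line enters the allele-specific analysis only if:

* **Heterozygous anchor**: a transcribed-region SNP with ≥3 reads supporting
  each allele in DNA and a DNA alternate allelic fraction within
  [0.25, 0.75]. The window is applied *inclusively* at both endpoints
  ("between 0.25 and 0.75" is ambiguous; inclusive is the permissive
  reading, and both bounds are configurable).
* **RNA coverage**: ≥8 total RNA reads at that anchor (total reads, not
  per-allele).
* **Copy number**: locus copy number within [1.0, 6.0]. "High-level
  amplification or deletion" has no standard numeric definition; these
  defaults exclude homozygous deletions and ≥6-copy gains, following common
  copy-number-call conventions, and are configurable.

The selection is monotone (tightening any threshold never grows the
evaluable set) and label-symmetric at default settings; both properties are
enforced by tests.

## Allelic-imbalance classification

With pseudocount 0.5 added to all four counts (a Haldane/continuity
correction, so zero minor-allele RNA reads — the typical monoallelic
signature — stay finite), the allelic odds alt/ref are formed in DNA and
RNA and the RNA/DNA odds ratio R computed. Dividing by the DNA odds removes
DNA-level imbalance from sampling noise or residual copy-number skew: R is
invariant under any common scaling of both odds. The fold imbalance
max(R, 1/R) is compared to a 10-fold cutoff with the `>=` comparator by
default; both the value and the comparator are configuration keys, because
"at least 10-fold" and ">10-fold" readings both occur and with pseudocount
0.5 an integer-count table can never sit exactly at 10 (with pseudocount
1.0 it can, which the boundary tests exploit).

Per-line aggregation is by unanimity: all passing anchors monoallelic →
MONOALLELIC, all biallelic → BIALLELIC, a mix → DISCORDANT, none →
UNEVALUABLE. Anchors are mutually unphased, so a vote could silently merge
inconsistent haplotype signals; DISCORDANT makes the conflict explicit.
DISCORDANT lines are excluded from contingency tables by default but remain
in every report, and a config flag (`discordant_as`) can reassign them.

## Promoter hotspot calling

Per site: depth < 8 → INSUFFICIENT; alternate reads ≥3 **and** alternate
fraction ≥10% → MUTANT; otherwise WILD_TYPE. Per line: any INSUFFICIENT
site → UNDETERMINED (the line drops out of promoter-status analyses and the
sufficient-coverage count); exactly one MUTANT site → MUTANT with that
label; two or more MUTANT sites → MUTANT with `multi_hit_flag` and a logged
warning. Hotspot mutual exclusivity is treated as an observation to
surface, not a filter — multi-hit lines are retained. The evidence
thresholds are package choices (no published numeric rule exists) that echo
the anchor-SNP minimums; all are configurable.

## Exact statistics

**One-tailed 2×2 Fisher.** The hypergeometric upper tail
P(X ≥ a | margins) computed by summing pmf terms in log-factorial space
(`scipy.special.gammaln` + log-sum-exp). Orientation is part of the
contract, fixed a priori to the study hypothesis — row 1 promoter-mutant,
column 1 monoallelic, enrichment tail — never inferred from the data. The
implementation is verified against exact rational arithmetic on every 2×2
table with grand total ≤ 60.

**Fisher–Freeman–Halton r×c.** The exact generalization: p is the total
multivariate-hypergeometric probability of all margin-fixed tables no more
probable than the observed one. Probabilities are compared in log space
with relative tolerance 1e-9 so float rounding cannot reorder ties. When
the number of margin-fixed tables exceeds `max_tables`, a seeded
Monte-Carlo estimate takes over: tables are sampled from the margin-fixed
null with `scipy.stats.random_table` (Patefield/Boyett), the p-value is
estimated as (hits+1)/(B+1) — guaranteeing p ∈ (0,1] — and the standard
error is reported. Defaults are `max_tables = 200,000` and
`mc_replicates = 100,000`: enumeration beyond a few hundred thousand tables
costs minutes in pure Python while 100,000 replicates already give a
standard error ≤ 0.0016, far below any decision threshold the pipeline
uses; both knobs are configuration keys. Group×lineage tables drop lineage
columns empty in both groups (they carry no information under the
conditional null) but keep lineages present in only one group (they carry
the signal).

**Expression-level comparison.** A two-sided rank-sum test: exact
enumeration of rank assignments when the pooled sample is small (N ≤ 20)
and untied, otherwise the normal approximation with tie-corrected variance
(no continuity correction); an all-tied sample has zero rank variance and
returns p = 1. No multiple-testing correction is applied anywhere in the
pipeline.

**Cis-phasing concordance.** Subclone observations (promoter allele +
anchor allele per sequenced clone) are aggregated per line by majority among
mutant-promoter clones, with the conflict fraction reported and exact ties
rejected as ambiguous. Concordance of the cis allele with the expressed
allele across n lines is tested with the exact one-tailed binomial test
against chance (k of n at p = 0.5); with four fully concordant lines this
gives p = 0.5⁴ = 0.0625. A one-sample t-test on all-concordant indicator
data is degenerate (zero variance), which is why the binomial test is the
primary statistic here.

**Upstream window scan.** Proximal *cis* events are variant records within
the closed window [ATG, ATG + 10 kb] (upstream of the minus-strand gene =
increasing coordinate; anchor and length configurable). Enrichment of
"≥1 event" in unexplained-monoallelic lines (monoallelic, promoter
wild-type) versus biallelic lines uses the one-tailed Fisher test above.

## Synthetic cohorts

The generator produces cohorts with the statistical structure the analysis
assumes, plus a per-line truth table, so every stage is testable without
sequencing data. Per line: heterozygous anchors with DNA depth ~
Poisson(100) (minimum 1) split Binomial(depth, 0.5); RNA depth likewise,
split at 0.5 for biallelic lines or at `p_major_rna` (default 0.98) toward
the cis allele for monoallelic lines; symmetric per-read allele flipping at
`seq_error` (default 0.001; no third alleles, since the analysis is
biallelic throughout); promoter-mutant lines carry one hotspot site at
alternate fraction 0.5 (heterozygous somatic mutation) with the mutation in
cis with the expressed allele; all other hotspot sites are reference-only.
Copy number is 2.0 by default, with knobs to mark fractions of lines
amplified (8.0) or deleted (0.0) to exercise the exclusion filter. Lineages
are drawn independently of expression mode from a configurable composition.

Default group sizes mirror the analyzed cohort: 88 lines, of which 19
(21.6%) carry a promoter mutation and are monoallelic, 20 more are
monoallelic without one, and 49 are biallelic. **Noiseless mode** fixes
depths at their means, sets the major-allele fraction to 1 and the error
rate to 0; classification then recovers the truth exactly, promoter-mutant
lines are all called monoallelic, and the pipeline reports 39/88 = 44.3%
monoallelic with 19/39 = 48.7% explained and a one-tailed Fisher p of
7.7×10⁻⁹ — the reconstructible headline numbers. The stochastic default
(depth 100, `p_major_rna` 0.98) recovers ≥95% of true modes at n = 500.

What the generator does **not** emulate: reference-mapping bias in allele
counts, overdispersed (beta-binomial) read sampling, linked multi-anchor
haplotype structure, lineage-dependent monoallelic prevalence, and real
copy-number continua. Passing tests therefore demonstrate correctness of
the pipeline's logic and statistics under its stated model, not robustness
to those real-data artifacts.

## Numerical and I/O choices

All reports are byte-deterministic: stable column order, floats at 6
significant digits, `NA` for missing, LF endings; identical config + inputs
give identical bytes. Percentages in the cohort summary are reported to one
decimal place. Exit codes: 0 success, 2 validation error, 3 I/O error.
Test-suite problem sizes (exhaustive 2×2 totals ≤ 60, Freeman–Halton
enumeration up to ~2×10⁶ tables, Monte-Carlo at 2×10⁴ replicates, stochastic
recovery at n = 500) were chosen so the full suite runs in well under a
minute on a single CPU while still exercising every code path.

## Known limitations

* The anchor aggregation rule (unanimity + DISCORDANT) is a conservative
  package choice; no published rule exists for conflicting anchors.
* The promoter-call evidence thresholds and the copy-number window are
  package defaults, not published values; conclusions at those margins
  should be checked against their configurability.
* The Freeman–Halton Monte-Carlo path is an estimate; its standard error is
  always reported and the enumeration path is preferred whenever feasible.
* The upstream scan consumes a variant list; it does not detect structural
  rearrangements, and events beyond the 10-kb window are out of scope.
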