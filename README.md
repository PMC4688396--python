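# monotert

Integrative DNA+RNA detection of **monoallelic TERT expression** in cancer
cell-line cohorts, with promoter hotspot mutation calling and exact
association statistics.

Telomerase (*TERT*) reactivation is near-universal in cancer, and the
recurrent noncoding promoter mutations (C228T, C250T, and rarer variants at
chr5:1,295,191–1,295,250, hg19) are its most common genetic driver. Because
these mutations act in *cis* — they create an ETS-factor binding site on one
chromosome copy — they are expected to reactivate only the allele they sit
on. `monotert` implements the computational side of that analysis for anyone
with paired DNA/RNA allele-depth tables: it classifies each cell line's
*TERT* expression as monoallelic or biallelic from allele-specific read
counts, calls promoter hotspot mutation status from DNA depths, and tests
the association between the two with exact statistics. A truth-tracked
synthetic cohort generator makes every stage testable without access to any
sequencing data.

## The method

For each line, a heterozygous **anchor SNP** in the expressed regions of
*TERT* (≥3 reads per allele in DNA, alternate allelic fraction in
[0.25, 0.75]) with ≥8 RNA reads attributes expression to alleles. With a
Haldane pseudocount of 0.5 on all counts, the DNA-normalized allelic odds
ratio at an anchor is

    R = [(rna_alt + ½)/(rna_ref + ½)] / [(dna_alt + ½)/(dna_ref + ½)]

and the line is **monoallelic** when the fold imbalance max(R, 1/R) ≥ 10
(threshold, comparator and pseudocount configurable). Lines with high-level
copy-number amplification or deletion of the locus are excluded.

Promoter status is called from DNA allele counts at the five hotspot
positions (six substitutions, since 1,295,228 carries both C>T and C>A); a
line with insufficient coverage at any hotspot is excluded from promoter
analyses. The promoter-status × expression-mode association uses the
one-tailed Fisher exact test (hypergeometric upper tail in log-factorial
space); lineage-distribution comparisons use the Fisher–Freeman–Halton
exact r×c test (full enumeration of margin-fixed tables, with a seeded
margin-preserving Monte-Carlo fallback); expression-level comparisons use a
two-sided rank-sum test; cis-phasing concordance across lines uses an exact
binomial test; and a 10-kb upstream window scan tests for proximal *cis*
events in unexplained-monoallelic lines. See `docs/methods.md` for details
and assumptions.

## Worked example

Simulate the deterministic 88-line reference cohort (19 promoter-mutant
monoallelic, 20 wild-type monoallelic, 49 biallelic; fixed 100× depth) and
run the pipeline:

```bash
monotert simulate --out-dir demo_cohort --seed 42 --noiseless
monotert run --anchors demo_cohort/anchors.tsv \
             --promoters demo_cohort/promoter_sites.tsv \
             --metadata demo_cohort/metadata.tsv \
             --out-dir demo_out
```

which prints:

```
evaluable lines: 88/88
monoallelic: 39 (44.3%)
promoter-mutant among evaluable: 19; mutant∩monoallelic: 19 (48.7% of monoallelic)
promoter_vs_mode_fisher: p = 7.74e-09 [fisher-exact-one-tailed]
lineage_mutant_vs_biallelic_ffh: p = 0.808 [freeman-halton]
lineage_wt_mono_vs_biallelic_ffh: p = 0.225 [freeman-halton]
expression_mutant_vs_wt: p = 1 [rank-sum-normal]
expression_mono_vs_biallelic: p = 1 [rank-sum-normal]
```

Reading the output: 39 of 88 evaluable lines (44.3%) show ≥10-fold
DNA-normalized allelic imbalance in RNA; every one of the 19 promoter-mutant
lines is among them, so promoter mutations account for 48.7% of the
monoallelic lines, and the 2×2 association [[19,0],[20,49]] has a one-tailed
Fisher p of 7.7×10⁻⁹. Lineage labels in this cohort are drawn independently
of expression mode, so the Freeman–Halton lineage tests are correctly
non-significant, as are the expression-level comparisons. `demo_out/`
contains the per-line report, exclusion log, statistics report (with the
underlying contingency tables) and a JSON summary; outputs are byte-identical
across re-runs.

The same analyses are available as a library (`monotert.run_pipeline`,
`monotert.fisher_exact_one_tailed`, `monotert.freeman_halton_exact`,
`monotert.simulate_cohort`, …), and `monotert stats --table t.tsv --test ffh`
runs the exact tests on any count table.

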