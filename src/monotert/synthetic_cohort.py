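"""Synthetic cohort generator with ground truth.

Emulates the statistical structure the downstream analysis assumes in a
DNA+RNA-sequenced cancer cell-line cohort: heterozygous transcribed anchor
SNPs with DNA depths binomially split at allele fraction 0.5; RNA depths
split at 0.5 for biallelic lines or skewed toward the cis (expressed) allele
for monoallelic lines; heterozygous promoter hotspot mutations placed in cis
with the overexpressed allele; lineage labels drawn from a configurable
composition; and a truth table recording every line's true expression mode,
promoter genotype, and cis allele per anchor.

Default conditions mirror the analyzed cohort: 88 lines of which 19 carry a
promoter hotspot mutation (all monoallelic), a further 20 are monoallelic
without a promoter mutation, and 49 are biallelic; sequencing depth ~100× in
both assays. In noiseless mode depths are fixed (not sampled), the RNA
major-allele fraction is 1, and the error rate is 0, so classification is
exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .io_model import (
    AlleleDepth,
    AnchorSNPObservation,
    CellLineRecord,
    Cohort,
    ConfigError,
    DEFAULT_HOTSPOT_CATALOG,
    DEFAULT_TARGET_GENE,
    GenomicLocus,
    HotspotCatalog,
    PromoterSiteObservation,
    TargetGene,
    write_report,
    write_simple_vcf,
)

MONOALLELIC = "MONOALLELIC"
BIALLELIC = "BIALLELIC"
WT = "WT"

#: Lineage composition used by default: a broad-spectrum cohort with a few
#: lineages known to lean monoallelic strongly represented.
DEFAULT_LINEAGE_WEIGHTS: dict[str, float] = {
    "melanoma": 0.15,
    "lung": 0.20,
    "haematopoietic": 0.20,
    "pancreas": 0.10,
    "urinary_tract": 0.10,
    "other": 0.25,
}

#: Relative frequencies of the hotspot labels among promoter-mutant lines
#: (the two canonical substitutions dominate; the C>A change is rare).
DEFAULT_MUTATION_LABEL_WEIGHTS: dict[str, float] = {
    "C228T": 0.65,
    "C250T": 0.30,
    "C228A": 0.05,
}

#: Anchor loci inside the expressed regions of TERT (hg19). The first is the
#: canonical exon-2 synonymous SNP rs2736098.
DEFAULT_ANCHOR_LOCI: tuple[tuple[str, int, str, str], ...] = (
    ("rs2736098", 1_294_086, "G", "A"),
    ("rs2736100", 1_286_516, "A", "C"),
    ("rs33954691", 1_278_895, "C", "T"),
    ("synth_anchor_4", 1_271_500, "G", "T"),
    ("synth_anchor_5", 1_264_200, "T", "C"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one simulated cohort.

    ``frac_promoter_mutant`` lines carry a heterozygous hotspot mutation and
    are monoallelic with the mutation in cis with the expressed allele;
    ``frac_wt_monoallelic`` further lines are monoallelic without a promoter
    mutation; the rest are biallelic. ``p_major_rna`` is the RNA read
    fraction on the expressed allele of monoallelic lines (must be 1 in
    noiseless mode); ``seq_error`` flips each read's allele symmetrically.
    """

    n_lines: int = 88
    lineage_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LINEAGE_WEIGHTS))
    frac_promoter_mutant: float = 19 / 88
    frac_wt_monoallelic: float = 20 / 88
    dna_depth_mean: int = 100
    rna_depth_mean: int = 100
    p_major_rna: float = 0.98
    seq_error: float = 0.001
    anchors_per_line: int = 1
    frac_cn_amplified: float = 0.0
    frac_cn_deleted: float = 0.0
    noiseless: bool = False
    seed: int = 0
    mutation_label_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MUTATION_LABEL_WEIGHTS))

    def validate(self) -> None:
        if self.n_lines < 0:
            raise ConfigError(f"n_lines must be >= 0, got {self.n_lines}")
        for name in ("frac_promoter_mutant", "frac_wt_monoallelic",
                     "frac_cn_amplified", "frac_cn_deleted"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.frac_promoter_mutant + self.frac_wt_monoallelic > 1.0 + 1e-12:
            raise ConfigError("frac_promoter_mutant + frac_wt_monoallelic must be <= 1")
        if not (0.5 <= self.p_major_rna <= 1.0):
            raise ConfigError(f"p_major_rna must be in [0.5, 1], got {self.p_major_rna}")
        if not (0.0 <= self.seq_error < 0.5):
            raise ConfigError(f"seq_error must be in [0, 0.5), got {self.seq_error}")
        if self.dna_depth_mean < 1 or self.rna_depth_mean < 1:
            raise ConfigError("depth means must be positive")
        if self.anchors_per_line < 0:
            raise ConfigError("anchors_per_line must be >= 0")
        if self.anchors_per_line > len(DEFAULT_ANCHOR_LOCI):
            raise ConfigError(
                f"anchors_per_line must be <= {len(DEFAULT_ANCHOR_LOCI)}"
            )
        if self.noiseless and (self.p_major_rna != 1.0 or self.seq_error != 0.0):
            raise ConfigError("noiseless mode requires p_major_rna = 1 and seq_error = 0")
        weights = list(self.lineage_weights.values())
        if not weights or any(w < 0 for w in weights) or sum(weights) <= 0:
            raise ConfigError("lineage_weights must be non-negative and sum to > 0")


def noiseless_reference_config(seed: int = 42) -> SimulationConfig:
    """The deterministic reference cohort: 88 lines (19 mutant monoallelic,
    20 wild-type monoallelic, 49 biallelic), fixed depth 100, one anchor."""
    return SimulationConfig(
        n_lines=88,
        frac_promoter_mutant=19 / 88,
        frac_wt_monoallelic=20 / 88,
        dna_depth_mean=100,
        rna_depth_mean=100,
        p_major_rna=1.0,
        seq_error=0.0,
        anchors_per_line=1,
        noiseless=True,
        seed=seed,
    )


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated line.

    ``cis_allele`` maps each anchor snp_id to the allele (REF/ALT) on the
    expressed haplotype — for promoter-mutant lines, the haplotype carrying
    the mutation. Promoter-mutant lines are always truly monoallelic.
    """

    line_id: str
    true_mode: str
    promoter_genotype: str  # "WT" or a hotspot label
    cis_allele: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.promoter_genotype != WT and self.true_mode != MONOALLELIC:
            raise ConfigError(
                f"{self.line_id}: promoter-mutant lines must be monoallelic by construction"
            )


def _apply_seq_error(ref: int, alt: int, error: float, rng: np.random.Generator) -> tuple[int, int]:
    if error <= 0:
        return ref, alt
    ref_flips = int(rng.binomial(ref, error))
    alt_flips = int(rng.binomial(alt, error))
    return ref - ref_flips + alt_flips, alt - alt_flips + ref_flips


def _split_depth(depth: int, p_alt: float, noiseless: bool, rng: np.random.Generator) -> tuple[int, int]:
    """Return (ref, alt) counts for a site of given depth and alt fraction."""
    if noiseless:
        alt = round(depth * p_alt)
    else:
        alt = int(rng.binomial(depth, p_alt))
    return depth - alt, alt


def _draw_depth(mean: int, noiseless: bool, rng: np.random.Generator) -> int:
    if noiseless:
        return mean
    return max(1, int(rng.poisson(mean)))


def simulate_cohort(
    config: SimulationConfig,
    target_gene: TargetGene = DEFAULT_TARGET_GENE,
    catalog: HotspotCatalog = DEFAULT_HOTSPOT_CATALOG,
) -> tuple[Cohort, list[TruthRecord]]:
    """Simulate a cohort plus its ground truth.

    Group sizes are exact (rounded from the configured fractions); group
    membership, lineages, cis alleles, mutation labels and all read counts
    are drawn from a single generator seeded with ``config.seed``, so the
    same config yields byte-identical cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_lines
    n_mut = round(config.frac_promoter_mutant * n)
    n_wt_mono = round(config.frac_wt_monoallelic * n)

    # group assignment: permute line indices, first n_mut are promoter-mutant
    # monoallelic, next n_wt_mono wild-type monoallelic, rest biallelic
    order = rng.permutation(n)
    group_of = {}
    for rank, idx in enumerate(order):
        if rank < n_mut:
            group_of[idx] = "mut"
        elif rank < n_mut + n_wt_mono:
            group_of[idx] = "wt_mono"
        else:
            group_of[idx] = "bi"

    lineage_labels = list(config.lineage_weights.keys())
    lineage_p = np.array([config.lineage_weights[k] for k in lineage_labels], dtype=float)
    lineage_p = lineage_p / lineage_p.sum()

    mut_labels = list(config.mutation_label_weights.keys())
    mut_p = np.array([config.mutation_label_weights[k] for k in mut_labels], dtype=float)
    mut_p = mut_p / mut_p.sum()

    # copy-number outliers (exercise the exclusion filter when requested)
    n_amp = round(config.frac_cn_amplified * n)
    n_del = round(config.frac_cn_deleted * n)
    cn_order = rng.permutation(n)
    amplified = set(cn_order[:n_amp].tolist())
    deleted = set(cn_order[n_amp:n_amp + n_del].tolist())

    anchor_loci = DEFAULT_ANCHOR_LOCI[: config.anchors_per_line]

    lines: list[CellLineRecord] = []
    truth: list[TruthRecord] = []
    for i in range(n):
        line_id = f"LINE{i:04d}"
        group = group_of[i]
        lineage = lineage_labels[int(rng.choice(len(lineage_labels), p=lineage_p))]
        if i in amplified:
            copy_number = 8.0
        elif i in deleted:
            copy_number = 0.0
        else:
            copy_number = 2.0
        expression_level = 20.0 if config.noiseless else float(rng.lognormal(3.0, 0.5))
        monoallelic = group in ("mut", "wt_mono")

        cis: dict[str, str] = {}
        anchors = []
        for snp_id, pos, ref, alt in anchor_loci:
            cis_allele = "ALT" if rng.random() < 0.5 else "REF"
            cis[snp_id] = cis_allele
            dna_depth = _draw_depth(config.dna_depth_mean, config.noiseless, rng)
            dna_ref, dna_alt = _split_depth(dna_depth, 0.5, config.noiseless, rng)
            rna_depth = _draw_depth(config.rna_depth_mean, config.noiseless, rng)
            if monoallelic:
                p_alt = config.p_major_rna if cis_allele == "ALT" else 1.0 - config.p_major_rna
            else:
                p_alt = 0.5
            rna_ref, rna_alt = _split_depth(rna_depth, p_alt, config.noiseless, rng)
            dna_ref, dna_alt = _apply_seq_error(dna_ref, dna_alt, config.seq_error, rng)
            rna_ref, rna_alt = _apply_seq_error(rna_ref, rna_alt, config.seq_error, rng)
            anchors.append(AnchorSNPObservation(
                snp_id=snp_id,
                locus=GenomicLocus(target_gene.chrom, pos, ref, alt),
                dna=AlleleDepth(dna_ref, dna_alt),
                rna=AlleleDepth(rna_ref, rna_alt),
            ))

        if group == "mut":
            mutation_label = mut_labels[int(rng.choice(len(mut_labels), p=mut_p))]
        else:
            mutation_label = WT
        promoter_sites = []
        for entry in catalog.entries:
            depth = _draw_depth(config.dna_depth_mean, config.noiseless, rng)
            if entry.label == mutation_label:
                # heterozygous somatic mutation: alt fraction 0.5
                p_ref, p_alt_count = _split_depth(depth, 0.5, config.noiseless, rng)
            else:
                p_ref, p_alt_count = depth, 0
            p_ref, p_alt_count = _apply_seq_error(p_ref, p_alt_count, config.seq_error, rng)
            promoter_sites.append(PromoterSiteObservation(
                locus=entry.locus, dna=AlleleDepth(p_ref, p_alt_count)
            ))

        lines.append(CellLineRecord(
            line_id=line_id,
            lineage=lineage,
            copy_number=copy_number,
            expression_level=expression_level,
            anchors=tuple(anchors),
            promoter_sites=tuple(promoter_sites),
        ))
        truth.append(TruthRecord(
            line_id=line_id,
            true_mode=MONOALLELIC if monoallelic else BIALLELIC,
            promoter_genotype=mutation_label,
            cis_allele=cis,
        ))
    return Cohort(lines=tuple(lines), target_gene=target_gene), truth


def write_truth_table(truth: Sequence[TruthRecord], path: str | Path) -> None:
    """Write the truth table TSV; cis alleles encoded as 'snp=ALLELE' pairs."""
    rows = [
        {
            "line_id": t.line_id,
            "true_mode": t.true_mode,
            "promoter_genotype": t.promoter_genotype,
            "cis_allele": ";".join(f"{k}={v}" for k, v in t.cis_allele.items()),
        }
        for t in truth
    ]
    write_report(rows, path, columns=["line_id", "true_mode", "promoter_genotype", "cis_allele"])


def inject_upstream_events(
    cohort: Cohort,
    truth: Sequence[TruthRecord],
    frac_with_event: float,
    window: tuple[int, int],
    seed: int,
    path: str | Path,
    line_ids: Optional[Sequence[str]] = None,
) -> list[str]:
    """Write a VCF in which a fraction of lines carry ≥1 variant in ``window``.

    ``window`` is a closed (start, end) interval on the target gene's
    chromosome. Lines are drawn without replacement from ``line_ids``
    (default: all cohort lines); the chosen count is round(frac × n).
    Returns the chosen line ids.
    """
    if not (0.0 <= frac_with_event <= 1.0):
        raise ConfigError(f"frac_with_event must be in [0, 1], got {frac_with_event}")
    lo, hi = window
    if hi < lo:
        raise ConfigError(f"invalid window {window}")
    rng = np.random.default_rng(seed)
    pool = list(line_ids) if line_ids is not None else [ln.line_id for ln in cohort.lines]
    k = round(frac_with_event * len(pool))
    chosen = sorted(rng.choice(pool, size=k, replace=False).tolist()) if k else []
    bases = "ACGT"
    records = []
    used_pos = set()
    for lid in chosen:
        pos = int(rng.integers(lo, hi + 1))
        while pos in used_pos:  # keep records distinct for readability
            pos = int(rng.integers(lo, hi + 1))
        used_pos.add(pos)
        ref = bases[int(rng.integers(4))]
        alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
        records.append((cohort.target_gene.chrom, pos, ref, alt, frozenset([lid])))
    sample_ids = [ln.line_id for ln in cohort.lines]
    write_simple_vcf(path, sample_ids, records, contig=cohort.target_gene.chrom)
    return chosen
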