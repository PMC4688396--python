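"""Eligibility filters: heterozygous anchor detection, RNA coverage, copy number.

A cell line is evaluable for allele-specific expression only if it carries at
least one transcribed heterozygous "anchor" SNP — called heterozygous from DNA
read counts (≥3 reads supporting each allele, alternate allelic fraction in
[0.25, 0.75], bounds inclusive) — with sufficient RNA coverage (≥8 reads) at
that anchor, and if the target locus has no high-level copy-number
amplification or deletion. All thresholds are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_model import (
    AlleleDepth,
    AnchorSNPObservation,
    CellLineRecord,
    Cohort,
    ValidationError,
)


@dataclass(frozen=True)
class SelectionThresholds:
    """Filter thresholds for anchor-SNP and line eligibility.

    ``cn_low``/``cn_high`` bound acceptable total copy number of the target
    locus; "high-level amplification or deletion" is not quantified in the
    source data conventions, so the defaults exclude homozygous deletion
    (<1 copy) and high-level gains (>6 copies).
    """

    min_ref_reads: int = 3
    min_alt_reads: int = 3
    dna_af_low: float = 0.25
    dna_af_high: float = 0.75
    min_rna_reads: int = 8
    cn_low: float = 1.0
    cn_high: float = 6.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dna_af_low < self.dna_af_high <= 1.0):
            raise ValidationError(
                f"require 0 <= dna_af_low < dna_af_high <= 1, got "
                f"[{self.dna_af_low}, {self.dna_af_high}]"
            )


@dataclass(frozen=True)
class ExclusionRecord:
    """Why a line was dropped: which filter failed, with detail."""

    line_id: str
    filter_failed: str
    detail: str


def is_heterozygous_anchor(dna: AlleleDepth, t: SelectionThresholds) -> bool:
    """True iff DNA counts support a heterozygous call.

    Requires ≥min_ref_reads and ≥min_alt_reads and an alternate allelic
    fraction within [dna_af_low, dna_af_high], both bounds inclusive.
    Raises at zero total depth (allelic fraction undefined).
    """
    if dna.total == 0:
        raise ValidationError("heterozygosity undefined at zero DNA depth")
    if dna.ref_count < t.min_ref_reads or dna.alt_count < t.min_alt_reads:
        return False
    af = dna.alt_fraction
    return t.dna_af_low <= af <= t.dna_af_high


def has_rna_coverage(rna: AlleleDepth, t: SelectionThresholds) -> bool:
    """True iff total RNA reads at the anchor meet the coverage minimum."""
    return rna.total >= t.min_rna_reads


def copy_number_pass(copy_number: float, t: SelectionThresholds) -> bool:
    """True iff the locus copy number lies in [cn_low, cn_high]."""
    if copy_number < 0:
        raise ValidationError(f"negative copy number: {copy_number}")
    return t.cn_low <= copy_number <= t.cn_high


def passing_anchors(
    line: CellLineRecord, t: SelectionThresholds
) -> list[AnchorSNPObservation]:
    """Anchors of ``line`` passing both the heterozygosity and RNA-coverage filters.

    Zero-DNA-depth anchors are silently non-passing (they cannot support a
    heterozygous call).
    """
    out = []
    for a in line.anchors:
        if a.dna.total == 0:
            continue
        if is_heterozygous_anchor(a.dna, t) and has_rna_coverage(a.rna, t):
            out.append(a)
    return out


def select_evaluable_lines(
    cohort: Cohort, t: SelectionThresholds
) -> tuple[list[CellLineRecord], Mapping[str, list[AnchorSNPObservation]], list[ExclusionRecord]]:
    """Partition the cohort into evaluable lines and an exclusion log.

    A line is evaluable iff its copy number passes and it has ≥1 anchor
    passing both per-anchor filters. The exclusion log records, per excluded
    line, the first filter responsible: ``copy_number``, then
    ``rna_coverage`` (a heterozygous anchor existed but lacked RNA reads),
    then ``no_heterozygous_anchor``.
    """
    evaluable: list[CellLineRecord] = []
    anchors_by_line: dict[str, list[AnchorSNPObservation]] = {}
    exclusions: list[ExclusionRecord] = []
    for line in cohort.lines:
        if not copy_number_pass(line.copy_number, t):
            exclusions.append(ExclusionRecord(
                line.line_id, "copy_number", f"copy_number={line.copy_number:g}"
            ))
            continue
        passing = passing_anchors(line, t)
        if passing:
            evaluable.append(line)
            anchors_by_line[line.line_id] = passing
            continue
        het = [a for a in line.anchors if a.dna.total > 0 and is_heterozygous_anchor(a.dna, t)]
        if het:
            exclusions.append(ExclusionRecord(
                line.line_id, "rna_coverage",
                f"{len(het)} heterozygous anchor(s), max RNA reads "
                f"{max(a.rna.total for a in het)}",
            ))
        else:
            exclusions.append(ExclusionRecord(
                line.line_id, "no_heterozygous_anchor", f"{len(line.anchors)} anchor(s) tested"
            ))
    return evaluable, anchors_by_line, exclusions


def write_exclusion_log(exclusions: Sequence[ExclusionRecord], path) -> None:
    from .io_model import write_report

    rows = [
        {"line_id": e.line_id, "filter_failed": e.filter_failed, "detail": e.detail}
        for e in exclusions
    ]
    write_report(rows, path, columns=["line_id", "filter_failed", "detail"])
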