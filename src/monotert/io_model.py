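"""Core domain types, cohort table I/O, VCF reading, and configuration.

The data model mirrors how allele-specific expression of *TERT* is assayed
in a cancer cell-line cohort: each line carries heterozygous "anchor" SNPs
in the expressed regions of the gene, with paired DNA and RNA allele read
depths, plus DNA allele depths at the recurrent promoter hotspot positions
on chr5 (hg19). All coordinates are 1-based hg19 throughout; intervals are
closed on both ends; hotspot alleles are stored exactly as written on the
plus strand (C>T at chr5:1,295,228 is the C228T label) and are never
rewritten to the opposite strand.

Cohorts are exchanged as three tab-separated tables (anchor, promoter,
metadata — schemas below) so that every downstream stage is testable from
plain text. Missing optional values are encoded as the literal ``NA``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger("monotert")

VALID_BASES = frozenset("ACGT")

ANCHOR_COLUMNS = (
    "line_id", "snp_id", "chrom", "pos", "ref", "alt",
    "dna_ref", "dna_alt", "rna_ref", "rna_alt",
)
PROMOTER_COLUMNS = ("line_id", "chrom", "pos", "ref", "alt", "dna_ref", "dna_alt")
METADATA_COLUMNS = ("line_id", "lineage", "copy_number", "expression_level")


class MonotertError(Exception):
    """Base class for all package errors."""


class ParseError(MonotertError):
    """A table or variant file could not be parsed; message names file/line/column."""


class ValidationError(MonotertError):
    """An input violated a domain invariant."""


class ConfigError(MonotertError):
    """An invalid configuration value."""


class DegenerateTableError(ValidationError):
    """A contingency table with zero grand total (or no rows to tabulate)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicLocus:
    """A biallelic SNV site: 1-based hg19 coordinate with ref/alt bases."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"locus position must be >= 1, got {self.pos}")
        if self.ref_base not in VALID_BASES or self.alt_base not in VALID_BASES:
            raise ValidationError(
                f"bases must be one of A/C/G/T, got {self.ref_base}>{self.alt_base}"
            )
        if self.ref_base == self.alt_base:
            raise ValidationError(f"ref and alt bases identical at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class AlleleDepth:
    """Reference/alternate read counts at one site in one assay (DNA or RNA)."""

    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValidationError(
                f"allele counts must be non-negative, got {self.ref_count}/{self.alt_count}"
            )

    @property
    def total(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def alt_fraction(self) -> float:
        """Alternate allelic fraction; undefined (error) at zero total depth."""
        if self.total == 0:
            raise ValidationError("allelic fraction undefined at zero total depth")
        return self.alt_count / self.total


@dataclass(frozen=True)
class AnchorSNPObservation:
    """A candidate heterozygous transcribed-region SNP with paired DNA/RNA depths."""

    snp_id: str
    locus: GenomicLocus
    dna: AlleleDepth
    rna: AlleleDepth


@dataclass(frozen=True)
class PromoterSiteObservation:
    """DNA allele depth at one promoter hotspot position for one line."""

    locus: GenomicLocus
    dna: AlleleDepth


@dataclass(frozen=True)
class HotspotEntry:
    locus: GenomicLocus
    label: str


@dataclass(frozen=True)
class HotspotCatalog:
    """Catalog of recurrent promoter hotspot substitutions.

    Entries are keyed by (position, alt base): chr5:1,295,228 legitimately
    carries two distinct hotspot alleles (C>T and C>A).
    """

    entries: tuple[HotspotEntry, ...]

    def __post_init__(self) -> None:
        keys = [(e.locus.pos, e.locus.alt_base) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValidationError("hotspot catalog has duplicate (position, alt) entries")

    def get(self, pos: int, alt_base: str) -> Optional[HotspotEntry]:
        for e in self.entries:
            if e.locus.pos == pos and e.locus.alt_base == alt_base:
                return e
        return None

    def by_label(self, label: str) -> HotspotEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise ValidationError(f"unknown hotspot label {label!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e.label for e in self.entries)


#: Translational start (ATG) coordinate of TERT, hg19. The canonical hotspots
#: C228T and C250T sit 124 and 146 bp upstream (the gene is minus-strand, so
#: upstream means increasing coordinate): 1295104+124 = 1295228, +146 = 1295250.
TERT_ATG_POS = 1_295_104

#: Default hotspot catalog: the five recurrent promoter positions on chr5.
#: Note a source discrepancy exists for the rare hotspot (1,295,191 vs
#: 1,295,161A>C); this catalog uses 1,295,191 with an A>C substitution —
#: see docs/methods.md. The catalog is configurable wherever it is consumed.
DEFAULT_HOTSPOT_CATALOG = HotspotCatalog(entries=(
    HotspotEntry(GenomicLocus("chr5", 1_295_191, "A", "C"), "A191C"),
    HotspotEntry(GenomicLocus("chr5", 1_295_228, "C", "T"), "C228T"),
    HotspotEntry(GenomicLocus("chr5", 1_295_228, "C", "A"), "C228A"),
    HotspotEntry(GenomicLocus("chr5", 1_295_242, "C", "T"), "C242T"),
    HotspotEntry(GenomicLocus("chr5", 1_295_243, "C", "T"), "C243T"),
    HotspotEntry(GenomicLocus("chr5", 1_295_250, "C", "T"), "C250T"),
))


@dataclass(frozen=True)
class TargetGene:
    """The gene under study: expressed-region intervals (closed, 1-based) and strand."""

    name: str
    chrom: str
    strand: str
    expressed_regions: tuple[tuple[int, int], ...]
    atg_pos: int

    def contains(self, pos: int) -> bool:
        return any(lo <= pos <= hi for lo, hi in self.expressed_regions)


#: TERT on hg19: minus strand, transcript body chr5:~1,253,167–1,295,183.
DEFAULT_TARGET_GENE = TargetGene(
    name="TERT",
    chrom="chr5",
    strand="-",
    expressed_regions=((1_253_167, 1_295_183),),
    atg_pos=TERT_ATG_POS,
)


@dataclass(frozen=True)
class CellLineRecord:
    """One cell line: lineage, target-locus copy number, observations."""

    line_id: str
    lineage: str
    copy_number: float
    expression_level: Optional[float]
    anchors: tuple[AnchorSNPObservation, ...] = ()
    promoter_sites: tuple[PromoterSiteObservation, ...] = ()

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValidationError(
                f"{self.line_id}: copy number must be non-negative, got {self.copy_number}"
            )


@dataclass(frozen=True)
class Cohort:
    lines: tuple[CellLineRecord, ...]
    target_gene: TargetGene = DEFAULT_TARGET_GENE

    def __post_init__(self) -> None:
        ids = [ln.line_id for ln in self.lines]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate line_id(s) in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.lines)

    def line(self, line_id: str) -> CellLineRecord:
        for ln in self.lines:
            if ln.line_id == line_id:
                return ln
        raise KeyError(line_id)


# ---------------------------------------------------------------------------
# TSV parsing helpers
# ---------------------------------------------------------------------------

def _read_tsv_rows(path: Path, columns: Sequence[str]) -> Iterable[tuple[int, dict]]:
    """Yield (line_number, row_dict) from a header-bearing TSV, validating the header."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file (header required)") from None
        if header != list(columns):
            raise ParseError(
                f"{path}:1: header mismatch, expected {list(columns)}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(columns):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(columns)} columns, got {len(row)}"
                )
            yield lineno, dict(zip(columns, row))


def _parse_nonneg_int(value: str, path: Path, lineno: int, column: str) -> int:
    try:
        v = int(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: column {column!r}: not an integer: {value!r}") from None
    if v < 0:
        raise ParseError(f"{path}:{lineno}: column {column!r}: negative count: {v}")
    return v


def _parse_float(value: str, path: Path, lineno: int, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: column {column!r}: not a number: {value!r}") from None


def _parse_locus(row: Mapping[str, str], path: Path, lineno: int) -> GenomicLocus:
    pos = _parse_nonneg_int(row["pos"], path, lineno, "pos")
    try:
        return GenomicLocus(row["chrom"], pos, row["ref"], row["alt"])
    except ValidationError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from None


# ---------------------------------------------------------------------------
# Cohort reading / writing
# ---------------------------------------------------------------------------

def read_cohort(
    anchor_table_path: str | Path,
    promoter_table_path: str | Path,
    metadata_table_path: str | Path,
    *,
    target_gene: TargetGene = DEFAULT_TARGET_GENE,
) -> Cohort:
    """Assemble a validated :class:`Cohort` from the three TSV tables.

    The metadata table defines the cohort roster; anchor or promoter rows
    referencing a line_id absent from metadata raise :class:`ValidationError`
    (a loud failure catches mismatched files). Lines absent from the anchor
    or promoter table simply carry empty observation lists.
    """
    anchor_path = Path(anchor_table_path)
    promoter_path = Path(promoter_table_path)
    metadata_path = Path(metadata_table_path)

    meta: dict[str, dict] = {}
    for lineno, row in _read_tsv_rows(metadata_path, METADATA_COLUMNS):
        line_id = row["line_id"]
        if line_id in meta:
            raise ValidationError(f"{metadata_path}:{lineno}: duplicate line_id {line_id!r}")
        expr = row["expression_level"]
        meta[line_id] = {
            "lineage": row["lineage"],
            "copy_number": _parse_float(row["copy_number"], metadata_path, lineno, "copy_number"),
            "expression_level": None if expr == "NA" else _parse_float(
                expr, metadata_path, lineno, "expression_level"
            ),
        }

    anchors: dict[str, list[AnchorSNPObservation]] = {k: [] for k in meta}
    for lineno, row in _read_tsv_rows(anchor_path, ANCHOR_COLUMNS):
        line_id = row["line_id"]
        if line_id not in meta:
            raise ValidationError(
                f"{anchor_path}:{lineno}: line_id {line_id!r} missing from metadata table"
            )
        locus = _parse_locus(row, anchor_path, lineno)
        anchors[line_id].append(AnchorSNPObservation(
            snp_id=row["snp_id"],
            locus=locus,
            dna=AlleleDepth(
                _parse_nonneg_int(row["dna_ref"], anchor_path, lineno, "dna_ref"),
                _parse_nonneg_int(row["dna_alt"], anchor_path, lineno, "dna_alt"),
            ),
            rna=AlleleDepth(
                _parse_nonneg_int(row["rna_ref"], anchor_path, lineno, "rna_ref"),
                _parse_nonneg_int(row["rna_alt"], anchor_path, lineno, "rna_alt"),
            ),
        ))

    promoters: dict[str, list[PromoterSiteObservation]] = {k: [] for k in meta}
    for lineno, row in _read_tsv_rows(promoter_path, PROMOTER_COLUMNS):
        line_id = row["line_id"]
        if line_id not in meta:
            raise ValidationError(
                f"{promoter_path}:{lineno}: line_id {line_id!r} missing from metadata table"
            )
        locus = _parse_locus(row, promoter_path, lineno)
        promoters[line_id].append(PromoterSiteObservation(
            locus=locus,
            dna=AlleleDepth(
                _parse_nonneg_int(row["dna_ref"], promoter_path, lineno, "dna_ref"),
                _parse_nonneg_int(row["dna_alt"], promoter_path, lineno, "dna_alt"),
            ),
        ))

    lines = tuple(
        CellLineRecord(
            line_id=line_id,
            lineage=m["lineage"],
            copy_number=m["copy_number"],
            expression_level=m["expression_level"],
            anchors=tuple(anchors[line_id]),
            promoter_sites=tuple(promoters[line_id]),
        )
        for line_id, m in meta.items()
    )
    logger.info("read cohort: %d lines from %s", len(lines), metadata_path)
    return Cohort(lines=lines, target_gene=target_gene)


def format_value(v: object) -> str:
    """Stable text rendering: 6 significant digits for floats, NA for None."""
    if v is None:
        return "NA"
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def write_report(report_rows: Sequence[Mapping[str, object]], path: str | Path,
                 columns: Optional[Sequence[str]] = None) -> None:
    """Write rows as a TSV with deterministic bytes.

    Column order comes from ``columns`` or the first row's key order; floats
    are rendered with 6 significant digits, ``None`` as ``NA``, line endings
    are LF. An empty row list with explicit ``columns`` yields a header-only
    file; an empty row list without columns raises :class:`ValidationError`.
    """
    if columns is None:
        if not report_rows:
            raise ValidationError("cannot infer columns from an empty report")
        columns = list(report_rows[0].keys())
    try:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(columns)
            for row in report_rows:
                writer.writerow([format_value(row[c]) for c in columns])
    except OSError as exc:
        raise MonotertError(f"cannot write report to {path}: {exc}") from exc


def write_cohort_tables(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the three cohort TSVs; returns {'anchor':…, 'promoter':…, 'metadata':…}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "anchor": out / "anchors.tsv",
        "promoter": out / "promoter_sites.tsv",
        "metadata": out / "metadata.tsv",
    }
    anchor_rows = [
        {
            "line_id": ln.line_id, "snp_id": a.snp_id, "chrom": a.locus.chrom,
            "pos": a.locus.pos, "ref": a.locus.ref_base, "alt": a.locus.alt_base,
            "dna_ref": a.dna.ref_count, "dna_alt": a.dna.alt_count,
            "rna_ref": a.rna.ref_count, "rna_alt": a.rna.alt_count,
        }
        for ln in cohort.lines for a in ln.anchors
    ]
    promoter_rows = [
        {
            "line_id": ln.line_id, "chrom": p.locus.chrom, "pos": p.locus.pos,
            "ref": p.locus.ref_base, "alt": p.locus.alt_base,
            "dna_ref": p.dna.ref_count, "dna_alt": p.dna.alt_count,
        }
        for ln in cohort.lines for p in ln.promoter_sites
    ]
    meta_rows = [
        {
            "line_id": ln.line_id, "lineage": ln.lineage,
            "copy_number": ln.copy_number, "expression_level": ln.expression_level,
        }
        for ln in cohort.lines
    ]
    write_report(anchor_rows, paths["anchor"], columns=list(ANCHOR_COLUMNS))
    write_report(promoter_rows, paths["promoter"], columns=list(PROMOTER_COLUMNS))
    write_report(meta_rows, paths["metadata"], columns=list(METADATA_COLUMNS))
    return paths


# ---------------------------------------------------------------------------
# VCF reading / writing (upstream-window scan support)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant (multi-allelic VCF records are split) with carriers.

    ``carriers`` is the set of sample (cell line) ids whose genotype contains
    this alternate allele.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    carriers: frozenset[str]


def read_variants_vcf(path: str | Path, region: tuple[str, int, int]) -> list[VariantRecord]:
    """Read VCF v4.x records whose POS falls in ``region`` (chrom, start, end; closed).

    Multi-allelic records are split into one record per alternate allele,
    each keeping only the samples that carry that allele.
    """
    import pysam

    chrom, start, end = region
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ParseError(f"{path}: not a readable VCF: {exc}") from exc
    records: list[VariantRecord] = []
    with vf:
        for rec in vf:
            if rec.chrom != chrom or rec.pos < start or rec.pos > end:
                continue
            for idx, alt in enumerate(rec.alts or (), start=1):
                carriers = frozenset(
                    name for name, sample in rec.samples.items()
                    if idx in (sample.get("GT") or ())
                )
                records.append(VariantRecord(rec.chrom, rec.pos, rec.ref, alt, carriers))
    return records


def write_simple_vcf(
    path: str | Path,
    sample_ids: Sequence[str],
    records: Sequence[tuple[str, int, str, str, frozenset[str] | set[str]]],
    contig: str = "chr5",
) -> None:
    """Write a minimal VCF v4.2 with GT-only sample columns (0/1 for carriers)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for chrom, pos, ref, alt, carriers in sorted(records, key=lambda r: (r[0], r[1], r[3])):
            gts = ["0/1" if s in carriers else "0/0" for s in sample_ids]
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# Flat key = value configuration files
# ---------------------------------------------------------------------------

def parse_config_file(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` text config; '#' starts a comment line."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out


def setup_logging(verbose: bool = False) -> None:
    level = logging.DEBUG if verbose else logging.INFO
    logging.basicConfig(level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s")
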