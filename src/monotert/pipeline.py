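"""End-to-end orchestration: selection → ASE classification → promoter calling
→ association statistics → optional upstream scan, with deterministic reports.

The cohort summary carries the headline quantities of the analysis: the
number of evaluable lines, how many are monoallelic (and the percentage, to
one decimal place), how many carry a promoter hotspot mutation, and what
fraction of the monoallelic lines the promoter mutations explain, together
with the exact association test results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import anchor_selection as sel
from . import ase_classifier as ase
from . import association_stats as stats
from . import promoter_caller as prom
from .io_model import (
    Cohort,
    ConfigError,
    DEFAULT_HOTSPOT_CATALOG,
    DegenerateTableError,
    HotspotCatalog,
    ValidationError,
    VariantRecord,
    parse_config_file,
    write_report,
)

logger = logging.getLogger("monotert")

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_IO = 3


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds and knobs of a pipeline run; every field has a config key."""

    selection: sel.SelectionThresholds = field(default_factory=sel.SelectionThresholds)
    promoter: prom.PromoterCallThresholds = field(default_factory=prom.PromoterCallThresholds)
    catalog: HotspotCatalog = DEFAULT_HOTSPOT_CATALOG
    ase_pseudocount: float = 0.5
    ase_fold_threshold: float = 10.0
    ase_comparator: str = ">="
    window_bp: int = 10_000
    ffh_max_tables: int = stats.DEFAULT_MAX_TABLES
    ffh_mc_replicates: int = stats.DEFAULT_MC_REPLICATES
    seed: int = 0
    #: None keeps DISCORDANT lines out of contingency tables (still reported);
    #: "MONOALLELIC"/"BIALLELIC" reassigns them.
    discordant_as: Optional[str] = None

    _KEY_MAP = {
        "min_ref_reads": ("selection", int), "min_alt_reads": ("selection", int),
        "dna_af_low": ("selection", float), "dna_af_high": ("selection", float),
        "min_rna_reads": ("selection", int),
        "cn_low": ("selection", float), "cn_high": ("selection", float),
        "promoter_min_depth": ("promoter", int),
        "promoter_min_alt_reads": ("promoter", int),
        "promoter_min_alt_fraction": ("promoter", float),
        "pseudocount": ("ase_pseudocount", float),
        "fold_threshold": ("ase_fold_threshold", float),
        "fold_comparator": ("ase_comparator", str),
        "window_bp": ("window_bp", int),
        "ffh_max_tables": ("ffh_max_tables", int),
        "ffh_mc_replicates": ("ffh_mc_replicates", int),
        "seed": ("seed", int),
        "discordant_as": ("discordant_as", str),
    }

    @classmethod
    def from_key_values(cls, kv: Mapping[str, str], base: "PipelineConfig | None" = None
                        ) -> "PipelineConfig":
        """Build a config from flat ``key = value`` pairs, over ``base`` defaults."""
        base = base or cls()
        sel_kwargs = dataclasses.asdict(base.selection)
        prom_kwargs = dataclasses.asdict(base.promoter)
        top: dict = {}
        for key, raw in kv.items():
            if key not in cls._KEY_MAP:
                raise ConfigError(f"unknown config key {key!r}")
            target, conv = cls._KEY_MAP[key]
            try:
                value = conv(raw)
            except ValueError:
                raise ConfigError(f"config key {key!r}: cannot parse {raw!r}") from None
            if target == "selection":
                sel_kwargs[key] = value
            elif target == "promoter":
                prom_kwargs[key.removeprefix("promoter_")] = value
            else:
                top[target] = value
        if top.get("discordant_as") in ("", "none", "None"):
            top["discordant_as"] = None
        return dataclasses.replace(
            base,
            selection=sel.SelectionThresholds(**sel_kwargs),
            promoter=prom.PromoterCallThresholds(**prom_kwargs),
            **top,
        )

    @classmethod
    def from_config_file(cls, path, base: "PipelineConfig | None" = None) -> "PipelineConfig":
        return cls.from_key_values(parse_config_file(path), base=base)


@dataclass(frozen=True)
class CohortSummary:
    """Headline counts, percentages (one decimal place), and test results."""

    n_total: int
    n_sufficient_promoter_coverage: int
    n_evaluable: int
    n_monoallelic: int
    n_biallelic: int
    n_discordant: int
    n_promoter_mutant: int
    n_mutant_and_monoallelic: int
    pct_monoallelic: float
    pct_monoallelic_explained: float
    tests: Mapping[str, stats.TestResult]

    def __post_init__(self) -> None:
        if self.n_monoallelic + self.n_biallelic + self.n_discordant != self.n_evaluable:
            raise ValidationError("mode counts do not sum to the evaluable count")
        if self.n_mutant_and_monoallelic > min(self.n_promoter_mutant, self.n_monoallelic):
            raise ValidationError("mutant∩monoallelic exceeds a marginal count")


@dataclass(frozen=True)
class PipelineResult:
    per_line_rows: tuple[dict, ...]
    summary: CohortSummary
    exclusions: tuple[sel.ExclusionRecord, ...]
    mode_calls: Mapping[str, ase.ExpressionModeCall]
    promoter_statuses: Mapping[str, prom.PromoterStatus]
    event_counts: Optional[Mapping[str, int]] = None


def _pct(numer: int, denom: int) -> float:
    return round(100.0 * numer / denom, 1) if denom else 0.0


def run_pipeline(
    cohort: Cohort,
    config: PipelineConfig | None = None,
    variants: Optional[Sequence[VariantRecord]] = None,
) -> PipelineResult:
    """Run the full analysis on an in-memory cohort.

    Stages run in order: evaluable-line selection, per-anchor imbalance and
    line classification, promoter hotspot calling (whole cohort), exact
    association statistics, and — when ``variants`` is given — the upstream
    cis-event scan. Deterministic given cohort + config (the seed only
    feeds the Freeman–Halton Monte-Carlo fallback).
    """
    config = config or PipelineConfig()

    evaluable, anchors_by_line, exclusions = sel.select_evaluable_lines(
        cohort, config.selection)
    if not evaluable:
        raise ValidationError("no evaluable lines after selection filters")
    logger.info("selection: %d/%d lines evaluable", len(evaluable), len(cohort))

    mode_calls: dict[str, ase.ExpressionModeCall] = {}
    for line in evaluable:
        results = [
            ase.imbalance_ratio(
                a.dna, a.rna,
                pseudocount=config.ase_pseudocount,
                fold_threshold=config.ase_fold_threshold,
                comparator=config.ase_comparator,
                snp_id=a.snp_id,
            )
            for a in anchors_by_line[line.line_id]
        ]
        mode_calls[line.line_id] = ase.classify_line(line.line_id, results)

    promoter_statuses: dict[str, prom.PromoterStatus] = {}
    for line in cohort.lines:
        promoter_statuses[line.line_id] = prom.call_line_from_observations(
            line.line_id, line.promoter_sites, config.promoter, config.catalog)

    # effective per-line mode used in tables (optionally reassigning DISCORDANT)
    def table_mode(line_id: str) -> str:
        mode = mode_calls[line_id].mode
        if mode == ase.DISCORDANT and config.discordant_as:
            return config.discordant_as
        return mode

    eval_ids = [ln.line_id for ln in evaluable]
    modes = {lid: mode_calls[lid].mode for lid in eval_ids}
    n_mono = sum(1 for m in modes.values() if m == ase.MONOALLELIC)
    n_bi = sum(1 for m in modes.values() if m == ase.BIALLELIC)
    n_disc = sum(1 for m in modes.values() if m == ase.DISCORDANT)
    n_mut = sum(1 for lid in eval_ids if promoter_statuses[lid].status == prom.MUTANT)
    n_mut_mono = sum(
        1 for lid in eval_ids
        if promoter_statuses[lid].status == prom.MUTANT and modes[lid] == ase.MONOALLELIC
    )
    n_suff = sum(
        1 for ln in cohort.lines
        if promoter_statuses[ln.line_id].status != prom.UNDETERMINED
    )

    tests: dict[str, stats.TestResult] = {}
    table_modes = {lid: table_mode(lid) for lid in eval_ids}

    # promoter status x expression mode (2x2, one-tailed)
    det_ids = [
        lid for lid in eval_ids
        if promoter_statuses[lid].status in (prom.MUTANT, prom.WILD_TYPE)
        and table_modes[lid] in (ase.MONOALLELIC, ase.BIALLELIC)
    ]
    counts = {
        (s, m): sum(
            1 for lid in det_ids
            if promoter_statuses[lid].status == s and table_modes[lid] == m
        )
        for s in (prom.MUTANT, prom.WILD_TYPE)
        for m in (ase.MONOALLELIC, ase.BIALLELIC)
    }
    assoc_table = stats.ContingencyTable(
        counts=(
            (counts[(prom.MUTANT, ase.MONOALLELIC)], counts[(prom.MUTANT, ase.BIALLELIC)]),
            (counts[(prom.WILD_TYPE, ase.MONOALLELIC)], counts[(prom.WILD_TYPE, ase.BIALLELIC)]),
        ),
        row_labels=("promoter_mutant", "promoter_wild_type"),
        col_labels=("monoallelic", "biallelic"),
    )
    try:
        res = stats.fisher_exact_one_tailed(assoc_table)
        tests["promoter_vs_mode_fisher"] = stats.TestResult(
            res.p_value, res.method, {**res.detail, "table": assoc_table.counts})
    except DegenerateTableError:
        logger.warning("promoter/mode table degenerate; association test skipped")

    # lineage distribution tests (Freeman-Halton)
    lineage_by_id = {ln.line_id: ln.lineage for ln in evaluable}
    status_by_id = {lid: promoter_statuses[lid].status for lid in eval_ids}
    for grouping in stats.GROUPINGS:
        try:
            table = stats.build_group_lineage_table(
                table_modes, status_by_id, lineage_by_id, grouping)
            res = stats.freeman_halton_exact(
                table,
                max_tables=config.ffh_max_tables,
                mc_replicates=config.ffh_mc_replicates,
                seed=config.seed,
            )
            tests[f"lineage_{grouping}_ffh"] = stats.TestResult(
                res.p_value, res.method, {**res.detail, "table": table.counts})
        except DegenerateTableError:
            logger.warning("lineage table degenerate for %s; test skipped", grouping)

    # expression-level comparisons (only when levels are recorded)
    expr = {ln.line_id: ln.expression_level for ln in evaluable
            if ln.expression_level is not None}
    mut_expr = [expr[lid] for lid in expr if status_by_id.get(lid) == prom.MUTANT]
    wt_expr = [expr[lid] for lid in expr if status_by_id.get(lid) == prom.WILD_TYPE]
    if mut_expr and wt_expr:
        tests["expression_mutant_vs_wt"] = stats.expression_level_comparison(mut_expr, wt_expr)
    mono_expr = [expr[lid] for lid in expr if table_modes.get(lid) == ase.MONOALLELIC]
    bi_expr = [expr[lid] for lid in expr if table_modes.get(lid) == ase.BIALLELIC]
    if mono_expr and bi_expr:
        tests["expression_mono_vs_biallelic"] = stats.expression_level_comparison(
            mono_expr, bi_expr)

    event_counts = None
    if variants is not None:
        event_counts, res = stats.upstream_window_scan(
            variants, cohort, table_modes, status_by_id, window_bp=config.window_bp)
        tests["upstream_scan_fisher"] = res

    summary = CohortSummary(
        n_total=len(cohort),
        n_sufficient_promoter_coverage=n_suff,
        n_evaluable=len(evaluable),
        n_monoallelic=n_mono,
        n_biallelic=n_bi,
        n_discordant=n_disc,
        n_promoter_mutant=n_mut,
        n_mutant_and_monoallelic=n_mut_mono,
        pct_monoallelic=_pct(n_mono, len(evaluable)),
        pct_monoallelic_explained=_pct(n_mut_mono, n_mono),
        tests=tests,
    )

    excluded_reason = {e.line_id: e for e in exclusions}
    per_line_rows = []
    for line in cohort.lines:
        lid = line.line_id
        call = mode_calls.get(lid)
        status = promoter_statuses[lid]
        exc = excluded_reason.get(lid)
        folds = [r.fold_imbalance for r in call.per_snp] if call else []
        per_line_rows.append({
            "line_id": lid,
            "lineage": line.lineage,
            "copy_number": line.copy_number,
            "evaluable": call is not None,
            "exclusion_reason": exc.filter_failed if exc else None,
            "n_passing_anchors": len(call.per_snp) if call else 0,
            "expression_mode": call.mode if call else None,
            "max_fold_imbalance": max(folds) if folds else None,
            "promoter_status": status.status,
            "mutation_label": status.mutation_label or None,
            "multi_hit_flag": status.multi_hit_flag,
            "expression_level": line.expression_level,
            "upstream_events": event_counts.get(lid) if event_counts else None,
        })

    return PipelineResult(
        per_line_rows=tuple(per_line_rows),
        summary=summary,
        exclusions=tuple(exclusions),
        mode_calls=mode_calls,
        promoter_statuses=promoter_statuses,
        event_counts=event_counts,
    )


PER_LINE_COLUMNS = [
    "line_id", "lineage", "copy_number", "evaluable", "exclusion_reason",
    "n_passing_anchors", "expression_mode", "max_fold_imbalance",
    "promoter_status", "mutation_label", "multi_hit_flag", "expression_level",
    "upstream_events",
]


def write_outputs(result: PipelineResult, out_dir) -> dict[str, Path]:
    """Write per-line report, exclusion log, statistics report and summary.

    Outputs are byte-identical across re-runs with identical inputs (stable
    column order, 6-significant-digit floats, LF endings, sorted JSON keys).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "per_line": out / "per_line_report.tsv",
        "exclusions": out / "exclusion_log.tsv",
        "stats": out / "stats_report.tsv",
        "summary": out / "summary.json",
    }
    write_report(list(result.per_line_rows), paths["per_line"], columns=PER_LINE_COLUMNS)
    sel.write_exclusion_log(list(result.exclusions), paths["exclusions"])
    stat_rows = []
    for name, res in result.summary.tests.items():
        detail = dict(res.detail)
        table = detail.pop("table", None)
        stat_rows.append({
            "test": name,
            "method": res.method,
            "p_value": res.p_value,
            "statistic": res.statistic,
            "table": json.dumps(table) if table is not None else None,
            "detail": json.dumps(detail, sort_keys=True, default=str),
        })
    write_report(stat_rows, paths["stats"],
                 columns=["test", "method", "p_value", "statistic", "table", "detail"])
    summary_dict = {
        f.name: getattr(result.summary, f.name)
        for f in dataclasses.fields(result.summary) if f.name != "tests"
    }
    summary_dict["tests"] = {
        name: {"p_value": res.p_value, "method": res.method}
        for name, res in result.summary.tests.items()
    }
    with open(paths["summary"], "w", newline="\n") as fh:
        json.dump(summary_dict, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
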