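"""Exact association statistics for promoter-mutation / expression-mode analyses.

Implements, from first principles in log-factorial space:

* the one-tailed 2×2 Fisher exact test (hypergeometric upper tail), oriented
  a priori toward enrichment of monoallelic expression among promoter-mutant
  lines;
* the Fisher–Freeman–Halton exact test for r×c tables — full enumeration of
  all margin-fixed tables when their number is tractable, otherwise a seeded
  Monte-Carlo estimate over margin-preserving random tables (Patefield/Boyett
  sampling via :func:`scipy.stats.random_table`) with a reported standard
  error;
* a two-sided rank-sum comparison of expression levels (exact rank
  enumeration for small untied samples, tie-corrected normal approximation
  otherwise);
* the 10-kb upstream cis-event scan: per-line variant counts in the window
  upstream of the translational start, tested for enrichment in
  unexplained-monoallelic lines with the one-tailed Fisher test.

Under the null of row/column independence conditional on the margins, the
probability of a table {n_ij} with row sums r_i, column sums c_j and grand
total N is the multivariate hypergeometric

    P = (Π_i r_i!)(Π_j c_j!) / (N! Π_ij n_ij!).

The Freeman–Halton p-value sums P over all margin-fixed tables no more
probable than the observed one; probabilities are compared in log space with
a relative tolerance of 1e-9 so float rounding cannot reorder ties.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import norm, rankdata, random_table

from .io_model import (
    Cohort,
    ConfigError,
    DegenerateTableError,
    ValidationError,
    VariantRecord,
)

#: Enumeration is attempted up to this many margin-fixed tables, then the
#: seeded Monte-Carlo path takes over. At the default replicate count the
#: Monte-Carlo standard error is ≤ 0.0016.
DEFAULT_MAX_TABLES = 200_000
DEFAULT_MC_REPLICATES = 100_000

#: Relative log-probability tolerance for the "no more probable" comparison.
LOG_PROB_RTOL = 1e-9


@dataclass(frozen=True)
class ContingencyTable:
    """An r×c grid of non-negative counts with optional axis labels."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.counts or not self.counts[0]:
            raise ValidationError("contingency table must have >= 1 row and column")
        ncol = len(self.counts[0])
        for row in self.counts:
            if len(row) != ncol:
                raise ValidationError("ragged contingency table")
            for v in row:
                if v < 0 or int(v) != v:
                    raise ValidationError(f"table entries must be non-negative integers, got {v}")

    @classmethod
    def from_array(cls, arr, row_labels=(), col_labels=()) -> "ContingencyTable":
        counts = tuple(tuple(int(v) for v in row) for row in np.asarray(arr))
        return cls(counts, tuple(row_labels), tuple(col_labels))

    @property
    def array(self) -> np.ndarray:
        return np.array(self.counts, dtype=np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.counts), len(self.counts[0])

    @property
    def total(self) -> int:
        return int(self.array.sum())


@dataclass(frozen=True)
class TestResult:
    """A p-value with the method that produced it and audit detail."""

    p_value: float
    method: str
    detail: Mapping[str, object] = field(default_factory=dict)
    statistic: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p-value out of (0, 1]: {self.p_value}")


# ---------------------------------------------------------------------------
# Fisher exact, one-tailed 2x2
# ---------------------------------------------------------------------------

def _log_hypergeom_pmf(k: np.ndarray, r1: int, c1: int, n: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeom(N=n, K=c1, draws=r1)."""
    k = np.asarray(k, dtype=np.float64)
    return (
        gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
        + gammaln(n - r1 + 1) - gammaln(c1 - k + 1) - gammaln(n - r1 - c1 + k + 1)
        + gammaln(c1 + 1) + gammaln(n - c1 + 1) - gammaln(n + 1)
    )


def fisher_exact_one_tailed(table: ContingencyTable) -> TestResult:
    """Upper-tail (enrichment) Fisher exact p for a 2×2 table.

    p = P(X ≥ a) for the hypergeometric distribution of cell (1,1) given
    fixed margins, computed by summing pmf terms in log space. Orientation
    is part of the contract: row 1 is the hypothesized-enriched group
    (promoter-mutant), column 1 the enriched outcome (monoallelic).
    """
    if table.shape != (2, 2):
        raise ValidationError(f"fisher_exact_one_tailed needs a 2x2 table, got {table.shape}")
    arr = table.array
    n = int(arr.sum())
    if n == 0:
        raise DegenerateTableError("2x2 table has zero grand total")
    a = int(arr[0, 0])
    r1 = int(arr[0].sum())
    c1 = int(arr[:, 0].sum())
    a_max = min(r1, c1)
    ks = np.arange(a, a_max + 1)
    p = float(np.exp(logsumexp(_log_hypergeom_pmf(ks, r1, c1, n))))
    p = min(p, 1.0)
    return TestResult(
        p_value=p,
        method="fisher-exact-one-tailed",
        detail={"tail_terms": int(a_max - a + 1), "orientation": "cell(1,1) >= observed"},
    )


# ---------------------------------------------------------------------------
# Fisher-Freeman-Halton exact r x c
# ---------------------------------------------------------------------------

class _TooManyTables(Exception):
    pass


def _iter_margin_tables(row_margins: Sequence[int], col_margins: Sequence[int],
                        max_tables: Optional[int] = None):
    """Yield every non-negative integer table with the given margins.

    Depth-first over rows; within a row, over cells bounded by the remaining
    column capacity. Raises :class:`_TooManyTables` past ``max_tables``.
    """
    nrow = len(row_margins)
    ncol = len(col_margins)
    count = 0
    table = np.zeros((nrow, ncol), dtype=np.int64)
    col_left = np.array(col_margins, dtype=np.int64)

    def fill_row(i: int):
        nonlocal count
        if i == nrow - 1:
            # last row forced by remaining column capacity
            if int(col_left.sum()) != row_margins[i]:
                return
            table[i] = col_left
            count += 1
            if max_tables is not None and count > max_tables:
                raise _TooManyTables
            yield table
            return
        yield from fill_cell(i, 0, row_margins[i])

    def fill_cell(i: int, j: int, remaining: int):
        if j == ncol - 1:
            if remaining <= col_left[j]:
                table[i, j] = remaining
                col_left[j] -= remaining
                yield from fill_row(i + 1)
                col_left[j] += remaining
            return
        for v in range(min(remaining, int(col_left[j])) + 1):
            table[i, j] = v
            col_left[j] -= v
            yield from fill_cell(i, j + 1, remaining - v)
            col_left[j] += v

    yield from fill_row(0)


def _log_table_prob_const(row_margins: np.ndarray, col_margins: np.ndarray) -> float:
    n = float(row_margins.sum())
    return float(
        gammaln(row_margins + 1).sum() + gammaln(col_margins + 1).sum() - gammaln(n + 1)
    )


def freeman_halton_exact(
    table: ContingencyTable,
    max_tables: int = DEFAULT_MAX_TABLES,
    mc_replicates: int = DEFAULT_MC_REPLICATES,
    seed: Optional[int] = None,
) -> TestResult:
    """Fisher–Freeman–Halton exact test for an r×c table.

    Full enumeration when the number of margin-fixed tables is at most
    ``max_tables`` (``detail['path'] = 'enumeration'``, with the enumerated
    table count and the total probability mass, which must be 1); otherwise
    a Monte-Carlo estimate over ``mc_replicates`` margin-preserving random
    tables (mandatory ``seed``), reported with its standard error and using
    the (hits+1)/(B+1) estimator so the p-value stays in (0, 1].
    """
    arr = table.array
    n = int(arr.sum())
    if n == 0:
        raise DegenerateTableError("table has zero grand total")
    row_margins = arr.sum(axis=1)
    col_margins = arr.sum(axis=0)
    if table.shape[0] == 1 or table.shape[1] == 1:
        return TestResult(1.0, "freeman-halton", detail={"path": "degenerate-single-margin"})

    const = _log_table_prob_const(row_margins, col_margins)
    lp_obs = const - float(gammaln(arr + 1).sum())
    tol = LOG_PROB_RTOL * max(1.0, abs(lp_obs))

    try:
        lps = []
        for t in _iter_margin_tables(row_margins.tolist(), col_margins.tolist(), max_tables):
            lps.append(const - float(gammaln(t + 1).sum()))
        lps = np.array(lps)
        probs = np.exp(lps)
        mask = lps <= lp_obs + tol
        p = float(probs[mask].sum())
        return TestResult(
            p_value=min(max(p, np.exp(lp_obs)), 1.0),
            method="freeman-halton",
            detail={
                "path": "enumeration",
                "n_tables": int(len(lps)),
                "prob_total": float(probs.sum()),
            },
        )
    except _TooManyTables:
        pass

    if seed is None:
        raise ConfigError(
            "freeman_halton_exact: Monte-Carlo fallback engaged "
            f"(> {max_tables} margin-fixed tables) but no seed was given"
        )
    rng = np.random.default_rng(seed)
    dist = random_table(row_margins, col_margins)
    samples = dist.rvs(mc_replicates, random_state=rng)
    lp_samples = const - gammaln(np.asarray(samples) + 1).sum(axis=(1, 2))
    hits = int(np.count_nonzero(lp_samples <= lp_obs + tol))
    phat = hits / mc_replicates
    se = math.sqrt(max(phat * (1 - phat), 1e-300) / mc_replicates)
    p = (hits + 1) / (mc_replicates + 1)
    return TestResult(
        p_value=min(p, 1.0),
        method="freeman-halton",
        detail={"path": "monte-carlo", "replicates": int(mc_replicates),
                "standard_error": se, "seed": int(seed)},
    )


# ---------------------------------------------------------------------------
# Group x lineage tables
# ---------------------------------------------------------------------------

GROUPINGS = ("mutant_vs_biallelic", "wt_mono_vs_biallelic")


def build_group_lineage_table(
    mode_calls: Mapping[str, str],
    promoter_statuses: Mapping[str, str],
    lineages: Mapping[str, str],
    grouping: str,
) -> ContingencyTable:
    """Build a 2×L group-by-lineage table for the lineage-distribution test.

    Row 1 is the monoallelic group of interest (promoter-mutant monoallelic
    for ``mutant_vs_biallelic``, promoter-wild-type monoallelic for
    ``wt_mono_vs_biallelic``); row 2 is all biallelic lines. Lineage columns
    with no line in either row are dropped; lineages present in only one
    group are kept.
    """
    if grouping not in GROUPINGS:
        raise ValidationError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")
    if grouping == "mutant_vs_biallelic":
        row1 = [
            lid for lid, mode in mode_calls.items()
            if mode == "MONOALLELIC" and promoter_statuses.get(lid) == "MUTANT"
        ]
        row1_label = "promoter_mutant_monoallelic"
    else:
        row1 = [
            lid for lid, mode in mode_calls.items()
            if mode == "MONOALLELIC" and promoter_statuses.get(lid) == "WILD_TYPE"
        ]
        row1_label = "promoter_wt_monoallelic"
    row2 = [lid for lid, mode in mode_calls.items() if mode == "BIALLELIC"]
    if not row1 and not row2:
        raise DegenerateTableError(f"no lines in either group for grouping {grouping!r}")
    used_lineages = sorted({lineages[lid] for lid in itertools.chain(row1, row2)})
    counts = []
    for group in (row1, row2):
        counts.append(tuple(
            sum(1 for lid in group if lineages[lid] == lin) for lin in used_lineages
        ))
    return ContingencyTable(
        counts=tuple(counts),
        row_labels=(row1_label, "biallelic"),
        col_labels=tuple(used_lineages),
    )


# ---------------------------------------------------------------------------
# Expression-level comparison (rank-sum)
# ---------------------------------------------------------------------------

def expression_level_comparison(
    values_group_a: Sequence[float], values_group_b: Sequence[float]
) -> TestResult:
    """Two-sided rank-sum comparison of two sets of expression levels.

    Exact rank-permutation p-value when there are no ties and the pooled
    sample is small (N ≤ 20); otherwise the normal approximation with tie
    correction on the rank-sum statistic W of group A (no continuity
    correction). All-tied samples have zero rank variance and return p = 1.
    """
    a = np.asarray(values_group_a, dtype=float)
    b = np.asarray(values_group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("expression comparison requires two non-empty groups")
    pooled = np.concatenate([a, b])
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    ranks = rankdata(pooled)
    w = float(ranks[:n_a].sum())
    mean_w = n_a * (n + 1) / 2.0
    has_ties = len(np.unique(pooled)) < n

    if not has_ties and n <= 20:
        all_ranks = np.arange(1, n + 1)
        dev_obs = abs(w - mean_w)
        total = math.comb(n, n_a)
        hits = sum(
            1 for combo in itertools.combinations(all_ranks, n_a)
            if abs(sum(combo) - mean_w) >= dev_obs - 1e-12
        )
        return TestResult(
            p_value=hits / total,
            method="rank-sum-exact",
            detail={"n_a": n_a, "n_b": n_b, "arrangements": total},
            statistic=w,
        )

    # tie-corrected variance of W under the null
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    var_w = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:
        return TestResult(1.0, "rank-sum-normal",
                          detail={"n_a": n_a, "n_b": n_b, "note": "zero variance (all tied)"},
                          statistic=w)
    z = (w - mean_w) / math.sqrt(var_w)
    p = min(2.0 * float(norm.sf(abs(z))), 1.0)
    return TestResult(
        p_value=max(p, 1e-300),
        method="rank-sum-normal",
        detail={"n_a": n_a, "n_b": n_b, "z": z, "tie_corrected": has_ties},
        statistic=w,
    )


# ---------------------------------------------------------------------------
# 10-kb upstream cis-event scan
# ---------------------------------------------------------------------------

def upstream_window(atg_pos: int, window_bp: int = 10_000) -> tuple[int, int]:
    """Closed interval upstream of a minus-strand gene's translational start.

    Upstream of a minus-strand gene lies at increasing coordinate, so the
    window is [atg_pos, atg_pos + window_bp], closed at both ends.
    """
    if window_bp <= 0:
        raise ConfigError(f"window_bp must be positive, got {window_bp}")
    return atg_pos, atg_pos + window_bp


def upstream_window_scan(
    variants: Sequence[VariantRecord],
    cohort: Cohort,
    mode_calls: Mapping[str, str],
    promoter_statuses: Mapping[str, str],
    window_bp: int = 10_000,
) -> tuple[dict[str, int], TestResult]:
    """Count per-line proximal cis events and test for enrichment.

    Events are variant records within the upstream window of the target
    gene. Enrichment of "has ≥1 event" in unexplained-monoallelic lines
    (monoallelic expression, promoter wild-type) versus biallelic lines is
    tested with the one-tailed Fisher exact test; rows are event presence,
    columns the two groups, the enrichment cell being (≥1 event,
    unexplained-monoallelic).
    """
    gene = cohort.target_gene
    lo, hi = upstream_window(gene.atg_pos, window_bp)
    counts = {lid: 0 for lid in mode_calls}
    for v in variants:
        if v.chrom != gene.chrom or not (lo <= v.pos <= hi):
            continue
        for carrier in v.carriers:
            if carrier in counts:
                counts[carrier] += 1
    unexplained = [
        lid for lid, mode in mode_calls.items()
        if mode == "MONOALLELIC" and promoter_statuses.get(lid) == "WILD_TYPE"
    ]
    biallelic = [lid for lid, mode in mode_calls.items() if mode == "BIALLELIC"]
    mono_with = sum(1 for lid in unexplained if counts[lid] > 0)
    bi_with = sum(1 for lid in biallelic if counts[lid] > 0)
    table = ContingencyTable(
        counts=(
            (mono_with, bi_with),
            (len(unexplained) - mono_with, len(biallelic) - bi_with),
        ),
        row_labels=("event", "no_event"),
        col_labels=("unexplained_monoallelic", "biallelic"),
    )
    if table.total == 0:
        return counts, TestResult(1.0, "fisher-exact-one-tailed",
                                  detail={"note": "no lines in either group"})
    result = fisher_exact_one_tailed(table)
    detail = dict(result.detail)
    detail["table"] = table.counts
    return counts, TestResult(result.p_value, result.method, detail)
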