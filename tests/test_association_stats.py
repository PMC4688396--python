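"""Exact tests: one-tailed Fisher, Freeman–Halton, rank-sum, upstream scan."""

import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats

import monotert as mt
from monotert.association_stats import (
    ContingencyTable,
    build_group_lineage_table,
    expression_level_comparison,
    fisher_exact_one_tailed,
    freeman_halton_exact,
    upstream_window,
    upstream_window_scan,
)

T = ContingencyTable


# ---------------------------------------------------------------------------
# one-tailed 2x2 Fisher
# ---------------------------------------------------------------------------

def test_headline_association_table_single_term_tail():
    """The promoter-status × expression-mode table assembled from the cohort's
    printed counts (19 mutant all monoallelic, 39 monoallelic, 88 evaluable)
    gives a single-term hypergeometric tail C(39,19)/C(88,19) ≈ 7.7e-9."""
    res = fisher_exact_one_tailed(T(((19, 0), (20, 49))))
    exact = Fraction(math.comb(39, 19), math.comb(88, 19))
    assert res.p_value == pytest.approx(float(exact), rel=1e-9)
    assert res.p_value < 1e-8


@pytest.mark.parametrize("table,expected", [
    (((5, 0), (0, 5)), Fraction(1, 252)),   # 1/C(10,5)
    (((1, 0), (0, 1)), Fraction(1, 2)),     # two margin-consistent tables
])
def test_fisher_closed_form_examples(table, expected):
    assert fisher_exact_one_tailed(T(table)).p_value == pytest.approx(float(expected))


def test_fisher_matches_exact_enumeration_all_tables_total_le_60():
    """The log-factorial implementation equals the exact rational
    hypergeometric tail on every 2×2 table with grand total ≤ 60 (iterated
    by margins: every table is one (n, r1, c1, a) tuple)."""
    from monotert.association_stats import _log_hypergeom_pmf

    for n in range(1, 61):
        for r1 in range(0, n + 1):
            for c1 in range(0, n + 1):
                a_min = max(0, r1 + c1 - n)
                a_max = min(r1, c1)
                # implementation: suffix log-sum-exp over the support
                lps = _log_hypergeom_pmf(np.arange(a_min, a_max + 1), r1, c1, n)
                p_impl = np.exp(np.logaddexp.accumulate(lps[::-1])[::-1])
                # oracle: exact integer suffix sums over a common denominator
                denom = math.comb(n, c1)
                numers = [math.comb(r1, k) * math.comb(n - r1, c1 - k)
                          for k in range(a_min, a_max + 1)]
                suffix = np.cumsum(np.array(numers[::-1], dtype=object))[::-1]
                p_oracle = np.array([num / denom for num in suffix], dtype=float)
                assert np.allclose(p_impl, p_oracle, rtol=1e-9, atol=0.0)


def test_fisher_spot_check_against_scipy():
    rng = np.random.default_rng(1)
    for _ in range(50):
        arr = rng.integers(0, 40, size=(2, 2))
        if arr.sum() == 0:
            continue
        res = fisher_exact_one_tailed(T.from_array(arr))
        ref = scipy.stats.fisher_exact(arr, alternative="greater").pvalue
        assert res.p_value == pytest.approx(float(ref), rel=1e-9)


def test_fisher_rejects_degenerate_and_wrong_shape():
    with pytest.raises(mt.DegenerateTableError):
        fisher_exact_one_tailed(T(((0, 0), (0, 0))))
    with pytest.raises(mt.ValidationError):
        fisher_exact_one_tailed(T(((1, 2, 3), (4, 5, 6))))


# ---------------------------------------------------------------------------
# Freeman-Halton
# ---------------------------------------------------------------------------

def test_ffh_hand_enumerated_2x2():
    # margins (4,4)/(4,4): cell(1,1)=a has weight C(4,a)C(4,4-a), total C(8,4)=70;
    # observed a=3 (weight 16) → tables no more probable: a ∈ {0,1,3,4} → 34/70
    res = freeman_halton_exact(T(((3, 1), (1, 3))))
    assert res.detail["path"] == "enumeration"
    assert res.p_value == pytest.approx(34 / 70, rel=1e-12)


def test_ffh_single_margin_table_is_one():
    assert freeman_halton_exact(T(((3, 5, 2),))).p_value == 1.0
    assert freeman_halton_exact(T(((3,), (5,)))).p_value == 1.0


def test_ffh_agrees_with_two_sided_fisher_on_2x2():
    rng = np.random.default_rng(2)
    for _ in range(40):
        arr = rng.integers(0, 25, size=(2, 2))
        if arr.sum() == 0:
            continue
        res = freeman_halton_exact(T.from_array(arr))
        ref = scipy.stats.fisher_exact(arr, alternative="two-sided").pvalue
        assert res.p_value == pytest.approx(float(ref), rel=1e-9)


def test_ffh_enumeration_probabilities_sum_to_one():
    rng = np.random.default_rng(3)
    checked = 0
    for _ in range(12):
        shape = (int(rng.integers(2, 4)), int(rng.integers(2, 5)))
        arr = rng.integers(0, 6, size=shape)
        if arr.sum() == 0:
            continue
        res = freeman_halton_exact(T.from_array(arr), max_tables=400_000, seed=0)
        if res.detail["path"] != "enumeration":
            continue
        checked += 1
        assert res.detail["prob_total"] == pytest.approx(1.0, abs=1e-10)
    assert checked >= 8


def test_ffh_monte_carlo_within_three_se_of_enumeration():
    """On 20 seeded random r×c tables the Monte-Carlo estimate falls within
    3 standard errors of full enumeration in at least 19 cases."""
    rng = np.random.default_rng(4)
    successes = 0
    for i in range(20):
        shape = (int(rng.integers(2, 4)), int(rng.integers(3, 5)))
        arr = rng.integers(0, 5, size=shape)
        arr.flat[0] += 1  # non-degenerate grand total
        enum = freeman_halton_exact(T.from_array(arr), max_tables=2_000_000)
        assert enum.detail["path"] == "enumeration"
        mc = freeman_halton_exact(
            T.from_array(arr), max_tables=0, mc_replicates=20_000, seed=100 + i)
        assert mc.detail["path"] == "monte-carlo"
        se = max(mc.detail["standard_error"], 1e-12)
        if abs(mc.p_value - enum.p_value) <= 3 * se + 2 / 20_000:
            successes += 1
    assert successes >= 19


def test_ffh_monte_carlo_requires_seed():
    with pytest.raises(mt.ConfigError):
        freeman_halton_exact(T(((3, 1), (1, 3))), max_tables=0, seed=None)


# ---------------------------------------------------------------------------
# group x lineage tables
# ---------------------------------------------------------------------------

def test_group_lineage_table_marginals_and_column_dropping():
    modes = {"A": "MONOALLELIC", "B": "MONOALLELIC", "C": "BIALLELIC",
             "D": "BIALLELIC", "E": "MONOALLELIC"}
    statuses = {"A": "MUTANT", "B": "WILD_TYPE", "C": "WILD_TYPE",
                "D": "MUTANT", "E": "MUTANT"}
    lineages = {"A": "melanoma", "B": "lung", "C": "lung",
                "D": "melanoma", "E": "melanoma"}
    table = build_group_lineage_table(modes, statuses, lineages, "mutant_vs_biallelic")
    # rows: mutant-monoallelic {A, E}, biallelic {C, D}; columns sorted lineages
    assert table.col_labels == ("lung", "melanoma")
    assert table.counts == ((0, 2), (1, 1))
    assert [sum(r) for r in table.counts] == [2, 2]

    wt = build_group_lineage_table(modes, statuses, lineages, "wt_mono_vs_biallelic")
    assert wt.counts == ((1, 0), (1, 1))

    with pytest.raises(mt.ValidationError):
        build_group_lineage_table(modes, statuses, lineages, "nope")


def test_single_lineage_cohort_gives_ffh_one():
    modes = {"A": "MONOALLELIC", "B": "BIALLELIC"}
    statuses = {"A": "MUTANT", "B": "WILD_TYPE"}
    lineages = {"A": "lung", "B": "lung"}
    table = build_group_lineage_table(modes, statuses, lineages, "mutant_vs_biallelic")
    assert table.shape == (2, 1)
    assert freeman_halton_exact(table).p_value == 1.0


# ---------------------------------------------------------------------------
# expression-level comparison
# ---------------------------------------------------------------------------

def test_ranksum_identical_groups_p_one():
    res = expression_level_comparison([1, 2, 3], [1, 2, 3])
    assert res.p_value == 1.0


def test_ranksum_separated_small_groups_exact():
    # fully separated n=3 vs 3: the most extreme of C(6,3)=20 rank splits,
    # attained twice (both directions) → two-sided p = 2/20 = 0.1
    res = expression_level_comparison([1, 2, 3], [10, 11, 12])
    assert res.method == "rank-sum-exact"
    assert res.p_value == pytest.approx(0.1)


def test_ranksum_all_tied_p_one():
    res = expression_level_comparison([5.0] * 4, [5.0] * 6)
    assert res.p_value == 1.0


def test_ranksum_large_samples_match_scipy_normal_approx():
    rng = np.random.default_rng(5)
    a = rng.normal(0, 1, 30).tolist()
    b = rng.normal(0.5, 1, 25).tolist()
    res = expression_level_comparison(a, b)
    ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic", use_continuity=False)
    assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-9)


def test_ranksum_empty_group_rejected():
    with pytest.raises(mt.ValidationError):
        expression_level_comparison([], [1.0])


# ---------------------------------------------------------------------------
# upstream window scan
# ---------------------------------------------------------------------------

def _scan_inputs(noiseless_cohort):
    cohort, truth = noiseless_cohort
    truth_by_id = {t.line_id: t for t in truth}
    modes = {t.line_id: t.true_mode for t in truth}
    statuses = {
        t.line_id: ("WILD_TYPE" if t.promoter_genotype == "WT" else "MUTANT")
        for t in truth
    }
    return cohort, truth_by_id, modes, statuses


def test_upstream_scan_no_variants_p_one(noiseless_cohort):
    cohort, _, modes, statuses = _scan_inputs(noiseless_cohort)
    counts, res = upstream_window_scan([], cohort, modes, statuses)
    assert all(c == 0 for c in counts.values())
    assert res.p_value == 1.0


def test_upstream_scan_perfect_enrichment_matches_closed_form(noiseless_cohort, tmp_path):
    """All unexplained-monoallelic lines carry an in-window event and no
    biallelic line does → p equals the single-term hypergeometric value."""
    cohort, truth_by_id, modes, statuses = _scan_inputs(noiseless_cohort)
    _, truth = noiseless_cohort
    unexplained = [lid for lid in modes
                   if modes[lid] == "MONOALLELIC" and statuses[lid] == "WILD_TYPE"]
    window = upstream_window(cohort.target_gene.atg_pos, 10_000)
    vcf = tmp_path / "events.vcf"
    mt.inject_upstream_events(cohort, truth, 1.0, window, seed=9, path=vcf,
                              line_ids=unexplained)
    variants = mt.read_variants_vcf(vcf, ("chr5", *window))
    counts, res = upstream_window_scan(variants, cohort, modes, statuses)
    n_u, n_b = len(unexplained), sum(1 for m in modes.values() if m == "BIALLELIC")
    assert (n_u, n_b) == (20, 49)
    expected = Fraction(1, math.comb(n_u + n_b, n_u))  # single-term tail
    assert res.p_value == pytest.approx(float(expected), rel=1e-9)
    assert all(counts[lid] >= 1 for lid in unexplained)


def test_upstream_window_far_boundary_counted(noiseless_cohort):
    """A variant exactly at the window's far boundary is inside (closed interval)."""
    cohort, _, modes, statuses = _scan_inputs(noiseless_cohort)
    lo, hi = upstream_window(cohort.target_gene.atg_pos, 10_000)
    some_line = next(iter(modes))
    at_edge = mt.VariantRecord("chr5", hi, "C", "T", frozenset([some_line]))
    past_edge = mt.VariantRecord("chr5", hi + 1, "C", "T", frozenset([some_line]))
    counts, _ = upstream_window_scan([at_edge, past_edge], cohort, modes, statuses)
    assert counts[some_line] == 1


def test_upstream_window_requires_positive_width():
    with pytest.raises(mt.ConfigError):
        upstream_window(1_295_104, 0)
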