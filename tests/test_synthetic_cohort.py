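"""Synthetic cohort generator: determinism, truth structure, noise model."""

import numpy as np
import pytest

import monotert as mt
from monotert.synthetic_cohort import SimulationConfig, noiseless_reference_config


def test_noiseless_reference_structure(noiseless_cohort):
    cohort, truth = noiseless_cohort
    assert len(cohort) == 88 and len(truth) == 88
    by_mode = {}
    for t in truth:
        key = (t.true_mode, t.promoter_genotype == "WT")
        by_mode[key] = by_mode.get(key, 0) + 1
    assert by_mode[("MONOALLELIC", False)] == 19   # promoter-mutant, all monoallelic
    assert by_mode[("MONOALLELIC", True)] == 20
    assert by_mode[("BIALLELIC", True)] == 49
    # fixed depth, exact heterozygous DNA split, zero RNA minor reads at
    # monoallelic anchors
    truth_by_id = {t.line_id: t for t in truth}
    for line in cohort.lines:
        (anchor,) = line.anchors
        assert anchor.dna.ref_count == anchor.dna.alt_count == 50
        assert anchor.rna.total == 100
        t = truth_by_id[line.line_id]
        if t.true_mode == "MONOALLELIC":
            minor = min(anchor.rna.ref_count, anchor.rna.alt_count)
            assert minor == 0
            major_allele = "ALT" if anchor.rna.alt_count > 0 else "REF"
            assert major_allele == t.cis_allele[anchor.snp_id]
        else:
            assert anchor.rna.ref_count == anchor.rna.alt_count == 50


def test_promoter_sites_cover_catalog_and_mark_mutants(noiseless_cohort):
    cohort, truth = noiseless_cohort
    truth_by_id = {t.line_id: t for t in truth}
    catalog = mt.DEFAULT_HOTSPOT_CATALOG
    for line in cohort.lines:
        keys = {(p.locus.pos, p.locus.alt_base) for p in line.promoter_sites}
        assert keys == {(e.locus.pos, e.locus.alt_base) for e in catalog.entries}
        genotype = truth_by_id[line.line_id].promoter_genotype
        for p in line.promoter_sites:
            entry = catalog.get(p.locus.pos, p.locus.alt_base)
            if entry.label == genotype:
                assert p.dna.alt_count == 50  # heterozygous somatic mutation
            else:
                assert p.dna.alt_count == 0


def test_same_seed_identical_output_different_seed_differs(tmp_path):
    cfg = SimulationConfig(n_lines=30, seed=7)
    c1, t1 = mt.simulate_cohort(cfg)
    c2, t2 = mt.simulate_cohort(cfg)
    assert c1 == c2 and t1 == t2
    p1 = mt.write_cohort_tables(c1, tmp_path / "a")
    p2 = mt.write_cohort_tables(c2, tmp_path / "b")
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes()
    c3, _ = mt.simulate_cohort(SimulationConfig(n_lines=30, seed=8))
    assert c3 != c1


def test_zero_lines_gives_empty_cohort():
    cohort, truth = mt.simulate_cohort(SimulationConfig(n_lines=0, seed=1))
    assert len(cohort) == 0 and truth == []


@pytest.mark.parametrize("kwargs", [
    dict(frac_promoter_mutant=0.7, frac_wt_monoallelic=0.5),
    dict(p_major_rna=0.4),
    dict(seq_error=0.6),
    dict(noiseless=True, p_major_rna=0.9),
    dict(anchors_per_line=-1),
])
def test_invalid_config_rejected(kwargs):
    with pytest.raises(mt.ConfigError):
        mt.simulate_cohort(SimulationConfig(seed=1, **kwargs))


def test_dna_alt_fraction_centered_at_half():
    """Marginal DNA alternate allelic fraction across anchors sits at 0.5
    within 3 standard errors of the binomial sampling model."""
    cfg = SimulationConfig(n_lines=400, anchors_per_line=2, seed=11)
    cohort, _ = mt.simulate_cohort(cfg)
    afs = np.array([a.dna.alt_fraction for ln in cohort.lines for a in ln.anchors])
    # each AF has variance ~ 1/(4*depth); use the empirical SE of the mean
    se = afs.std(ddof=1) / np.sqrt(afs.size)
    assert abs(afs.mean() - 0.5) < 3 * se + 1e-12


def test_copy_number_knob_marks_outliers():
    cfg = SimulationConfig(n_lines=50, frac_cn_amplified=0.1, frac_cn_deleted=0.1, seed=3)
    cohort, _ = mt.simulate_cohort(cfg)
    cns = [ln.copy_number for ln in cohort.lines]
    assert cns.count(8.0) == 5 and cns.count(0.0) == 5 and cns.count(2.0) == 40


def test_truth_record_enforces_mutant_monoallelic_rule():
    with pytest.raises(mt.ConfigError):
        mt.TruthRecord("L1", "BIALLELIC", "C228T", {})


# ---------------------------------------------------------------------------
# upstream event injection
# ---------------------------------------------------------------------------

def test_inject_upstream_events_fraction_and_window(noiseless_cohort, tmp_path):
    cohort, truth = noiseless_cohort
    atg = cohort.target_gene.atg_pos
    window = (atg, atg + 10_000)

    path0 = tmp_path / "none.vcf"
    chosen0 = mt.inject_upstream_events(cohort, truth, 0.0, window, seed=5, path=path0)
    assert chosen0 == []
    assert mt.read_variants_vcf(path0, ("chr5", *window)) == []

    subset = [ln.line_id for ln in cohort.lines[:5]]
    path1 = tmp_path / "all5.vcf"
    chosen1 = mt.inject_upstream_events(
        cohort, truth, 1.0, window, seed=5, path=path1, line_ids=subset)
    assert sorted(chosen1) == sorted(subset)
    records = mt.read_variants_vcf(path1, ("chr5", *window))
    carriers_with_event = set().union(*(r.carriers for r in records))
    assert carriers_with_event == set(subset)
    assert all(window[0] <= r.pos <= window[1] for r in records)

    path2 = tmp_path / "all5b.vcf"
    mt.inject_upstream_events(cohort, truth, 1.0, window, seed=5, path=path2,
                              line_ids=subset)
    assert path1.read_bytes() == path2.read_bytes()
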