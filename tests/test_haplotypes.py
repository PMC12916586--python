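import itertools
import math

import numpy as np
import pytest

from hlacc.haplotypes import (
    HaplotypeFreqTable,
    em_haplotypes,
    haplotype_assoc,
    ld_matrix,
    ld_pair,
)
from hlacc.simulate import GroupSpec, SynthConfig, simulate

from conftest import make_cohort


def hap_table(freqs, loci=("DRB1", "DQA1"), n_records=100):
    return HaplotypeFreqTable(
        tuple(loci), freqs, 0.0, [0.0], 1, True, n_records
    )


# ------------------------------------------------------------------------ EM


def test_em_on_homozygotes_is_direct_counting():
    cohort = make_cohort(
        [
            ("s1", {"A": ("A*01", "A*01"), "B": ("B*07", "B*07")}),
            ("s2", {"A": ("A*01", "A*01"), "B": ("B*07", "B*07")}),
            ("s3", {"A": ("A*02", "A*02"), "B": ("B*08", "B*08")}),
        ],
        ["A", "B"],
    )
    ft = em_haplotypes(cohort, ("A", "B"))
    assert ft.freqs[("A*01", "B*07")] == pytest.approx(2 / 3)
    assert ft.freqs[("A*02", "B*08")] == pytest.approx(1 / 3)
    assert ft.converged


def test_em_without_double_heterozygotes_is_exact():
    # single-het records have unambiguous phase: EM equals direct counts
    cohort = make_cohort(
        [
            ("s1", {"A": ("A*01", "A*02"), "B": ("B*07", "B*07")}),
            ("s2", {"A": ("A*01", "A*01"), "B": ("B*07", "B*08")}),
        ],
        ["A", "B"],
    )
    ft = em_haplotypes(cohort, ("A", "B"))
    assert ft.freqs[("A*01", "B*07")] == pytest.approx(2 / 4)
    assert ft.freqs[("A*02", "B*07")] == pytest.approx(1 / 4)
    assert ft.freqs[("A*01", "B*08")] == pytest.approx(1 / 4)


def test_em_double_heterozygote_symmetric_optima():
    """A single AB/ab double heterozygote has two equivalent phase
    resolutions; EM lands on one of them at 0.5/0.5 with the same
    likelihood under uniform init."""
    cohort = make_cohort([("s1", {"A": ("A*01", "A*02"), "B": ("B*07", "B*08")})], ["A", "B"])
    ft = em_haplotypes(cohort, ("A", "B"), init="uniform")
    assert sum(ft.freqs.values()) == pytest.approx(1.0, abs=1e-8)
    top = sorted(ft.freqs.values(), reverse=True)[:2]
    assert top == pytest.approx([0.5, 0.5], abs=1e-6)
    # either optimum gives likelihood 2 * 0.5 * 0.5
    assert ft.loglik == pytest.approx(math.log(0.5), abs=1e-6)


def test_em_loglik_monotone_and_freqs_normalized():
    truth = {
        ("DRB1*01", "DQA1*01"): 0.4,
        ("DRB1*02", "DQA1*02"): 0.3,
        ("DRB1*01", "DQA1*02"): 0.2,
        ("DRB1*03", "DQA1*01"): 0.1,
    }
    cfg = SynthConfig(
        300, 10, ("DRB1", "DQA1"),
        GroupSpec(haplotype_freqs=truth), GroupSpec(haplotype_freqs=truth), seed=3,
    )
    cases, _ = simulate(cfg)
    ft = em_haplotypes(cases, ("DRB1", "DQA1"))
    assert all(b >= a - 1e-9 for a, b in zip(ft.loglik_trace, ft.loglik_trace[1:]))
    assert sum(ft.freqs.values()) == pytest.approx(1.0, abs=1e-8)
    assert ft.converged


def test_em_parameter_recovery_within_binomial_error():
    truth = {
        ("DRB1*01", "DQA1*01"): 0.4,
        ("DRB1*02", "DQA1*02"): 0.3,
        ("DRB1*01", "DQA1*02"): 0.2,
        ("DRB1*03", "DQA1*01"): 0.1,
    }
    n = 500
    cfg = SynthConfig(
        n, 10, ("DRB1", "DQA1"),
        GroupSpec(haplotype_freqs=truth), GroupSpec(haplotype_freqs=truth), seed=9,
    )
    cases, _ = simulate(cfg)
    ft = em_haplotypes(cases, ("DRB1", "DQA1"))
    for hap, f in truth.items():
        se = math.sqrt(f * (1 - f) / (2 * n))
        assert abs(ft.freqs.get(hap, 0.0) - f) < 3 * se


def test_em_excludes_records_missing_a_requested_locus():
    cohort = make_cohort(
        [
            ("s1", {"A": ("A*01", "A*01"), "B": ("B*07", "B*07")}),
            ("s2", {"A": ("A*02", "A*02"), "B": None}),
        ],
        ["A", "B"],
    )
    ft = em_haplotypes(cohort, ("A", "B"))
    assert ft.n_records == 1
    assert ft.freqs == {("A*01", "B*07"): pytest.approx(1.0)}


def test_em_no_complete_records_rejected():
    cohort = make_cohort([("s1", {"A": ("A*01", "A*01"), "B": None})], ["A", "B"])
    with pytest.raises(ValueError):
        em_haplotypes(cohort, ("A", "B"))


# ------------------------------------------------------------------------ LD


def test_perfect_ld_duplicated_locus():
    ft = hap_table({("A*01", "A*01"): 0.6, ("A*02", "A*02"): 0.4})
    dp, rs = ld_pair(ft)
    assert dp == pytest.approx(1.0, abs=1e-9)
    assert rs == pytest.approx(1.0, abs=1e-9)


def test_complete_association_biallelic():
    ft = hap_table({("A*01", "B*07"): 0.5, ("A*02", "B*08"): 0.5})
    assert ld_pair(ft) == pytest.approx((1.0, 1.0))


def test_independent_loci_zero_ld():
    p = {"A*01": 0.6, "A*02": 0.4}
    q = {"B*07": 0.3, "B*08": 0.7}
    freqs = {(a, b): pa * qb for a, pa in p.items() for b, qb in q.items()}
    for weighting in ("frequency", "uniform"):
        dp, rs = ld_pair(hap_table(freqs), weighting=weighting)
        assert dp == pytest.approx(0.0, abs=1e-12)
        assert rs == pytest.approx(0.0, abs=1e-12)


def test_ld_pair_matches_biallelic_closed_form():
    # p_AB = 0.35, p_A = 0.5, q_B = 0.6 -> D = 0.05
    freqs = {
        ("A*01", "B*07"): 0.35, ("A*01", "B*08"): 0.15,
        ("A*02", "B*07"): 0.25, ("A*02", "B*08"): 0.25,
    }
    d = 0.05
    d_max = min(0.5 * 0.4, 0.5 * 0.6)
    rsq = d * d / (0.5 * 0.5 * 0.6 * 0.4)
    dp, rs = ld_pair(hap_table(freqs))
    # both weightings coincide for biallelic loci only in the uniform sense;
    # every allelic combination has the same |D'| and r^2 here
    assert dp == pytest.approx(d / d_max, abs=1e-12)
    assert rs == pytest.approx(rsq, abs=1e-12)


def test_monomorphic_locus_ld_undefined():
    ft = hap_table({("A*01", "B*07"): 0.5, ("A*01", "B*08"): 0.5})
    dp, rs = ld_pair(ft)
    assert math.isnan(dp) and math.isnan(rs)


def test_ld_entries_bounded():
    rng = np.random.default_rng(12)
    for _ in range(30):
        k1, k2 = rng.integers(2, 5, size=2)
        raw = rng.random((k1, k2))
        raw /= raw.sum()
        freqs = {
            (f"A*{i + 1:02d}", f"B*{j + 1:02d}"): raw[i, j]
            for i in range(k1)
            for j in range(k2)
        }
        for weighting in ("frequency", "uniform"):
            dp, rs = ld_pair(hap_table(freqs), weighting=weighting)
            assert 0.0 <= dp <= 1.0 + 1e-12
            assert 0.0 <= rs <= 1.0 + 1e-12


def test_ld_matrix_structure_and_block_ordering():
    class2 = {
        ("DRB1*01", "DQA1*01"): 0.5,
        ("DRB1*02", "DQA1*02"): 0.5,
    }
    rng_haps = {  # A independent of DPB1: product frequencies
        ("A*01", "DPB1*01"): 0.25, ("A*01", "DPB1*02"): 0.25,
        ("A*02", "DPB1*01"): 0.25, ("A*02", "DPB1*02"): 0.25,
    }
    four = {}
    for (d, q), f1 in class2.items():
        for (a, p), f2 in rng_haps.items():
            four[(a, d, q, p)] = f1 * f2
    cfg = SynthConfig(
        250, 10, ("A", "DRB1", "DQA1", "DPB1"),
        GroupSpec(haplotype_freqs=four), GroupSpec(haplotype_freqs=four), seed=21,
    )
    cases, _ = simulate(cfg)
    ld = ld_matrix(cases)
    assert ld.loci == ("A", "DRB1", "DQA1", "DPB1")  # chromosomal order
    assert np.allclose(ld.dprime, ld.dprime.T)
    assert np.allclose(np.diag(ld.dprime), 1.0)
    i, j = ld.loci.index("DRB1"), ld.loci.index("DQA1")
    a, b = ld.loci.index("A"), ld.loci.index("DPB1")
    assert ld.dprime[i, j] > ld.dprime[a, b]


# ------------------------------------------------------- haplotype association


def test_identical_frequency_tables_give_zero_chi2():
    freqs = {("DRB1*01", "DQA1*01"): 0.6, ("DRB1*02", "DQA1*02"): 0.4}
    rows = haplotype_assoc(hap_table(freqs), hap_table(freqs), 182, 700)
    assert all(r.chi2 == pytest.approx(0.0, abs=1e-9) for r in rows)


def test_case_only_haplotype_matches_allele_machinery(fixtures):
    """A haplotype at 0.10 in cases and absent in controls behaves exactly
    like a zero-cell allele with the same fractional counts."""
    from hlacc.association import TwoByTwo, haldane_adjust, odds_ratio_woolf, pearson_chi2

    case = hap_table({("DRB1*01", "DQA1*01"): 0.10, ("DRB1*02", "DQA1*02"): 0.90})
    ctrl = hap_table({("DRB1*02", "DQA1*02"): 1.0})
    rows = haplotype_assoc(case, ctrl, 182, 700)
    target = next(r for r in rows if r.allele == "DRB1*01~DQA1*01")
    t = haldane_adjust(TwoByTwo(18.2, 163.8, 0.0, 700.0))
    assert target.chi2 == pytest.approx(pearson_chi2(t), rel=1e-12)
    assert target.or_point == pytest.approx(odds_ratio_woolf(t)[0], rel=1e-12)
    assert target.zero_cell_adjusted and target.em_unstable


def test_group_swap_gives_reciprocal_ors():
    case = hap_table({("DRB1*01", "DQA1*01"): 0.3, ("DRB1*02", "DQA1*02"): 0.7})
    ctrl = hap_table({("DRB1*01", "DQA1*01"): 0.1, ("DRB1*02", "DQA1*02"): 0.9})
    fwd = {r.allele: r.or_point for r in haplotype_assoc(case, ctrl, 200, 200)}
    rev = {r.allele: r.or_point for r in haplotype_assoc(ctrl, case, 200, 200)}
    for hap in fwd:
        assert rev[hap] == pytest.approx(1 / fwd[hap], rel=1e-12)


def test_haplotype_assoc_rejects_locus_mismatch():
    a = hap_table({("DRB1*01", "DQA1*01"): 1.0}, loci=("DRB1", "DQA1"))
    b = hap_table({("DRB1*01", "DQB1*01"): 1.0}, loci=("DRB1", "DQB1"))
    with pytest.raises(ValueError):
        haplotype_assoc(a, b, 100, 100)
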