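import math

import numpy as np
import pytest
from scipy import stats

from hlacc.association import (
    AssocRow,
    TwoByTwo,
    UndefinedStatisticError,
    build_2x2,
    chi2_pvalue,
    fisher_two_sided,
    haberman_asr,
    haldane_adjust,
    locus_correct,
    odds_ratio_woolf,
    pearson_chi2,
    run_locus,
)
from hlacc.io import AlleleCountTable
from hlacc.nomenclature import parse_allele


def random_tables(n, seed, max_cell=200):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        a, b, c, d = rng.integers(1, max_cell, size=4)
        yield TwoByTwo(float(a), float(b), float(c), float(d))


# ---------------------------------------------------------------- 2x2 plumbing


def test_build_2x2_from_counts(fixtures):
    t = build_2x2(fixtures["B"], parse_allele("B*40:02:01"))
    assert (t.a, t.b, t.c, t.d) == (21, 161, 37, 663)
    t = build_2x2(fixtures["DQA1"], parse_allele("DQA1*05:05:01"))
    assert (t.a, t.b, t.c, t.d) == (28, 152, 0, 700)
    with pytest.raises(KeyError):
        build_2x2(fixtures["B"], parse_allele("B*99:99"))


@pytest.mark.parametrize(
    "cells, adjusted",
    [
        ((28, 152, 0, 700), (28.5, 152.5, 0.5, 700.5)),
        ((0, 182, 10, 690), (0.5, 182.5, 10.5, 690.5)),
        ((21, 161, 37, 663), (21, 161, 37, 663)),
    ],
)
def test_haldane_adjust(cells, adjusted):
    out = haldane_adjust(TwoByTwo(*cells))
    assert (out.a, out.b, out.c, out.d) == adjusted
    assert out.zero_cell_adjusted == (cells != adjusted)


# ----------------------------------------------------------------- chi-square


def test_chi2_matches_scipy_on_integer_tables():
    """Textbook Pearson formula agrees with the scipy contingency oracle."""
    for t in random_tables(1000, seed=42):
        expected = stats.chi2_contingency(
            [[t.a, t.b], [t.c, t.d]], correction=False
        ).statistic
        assert pearson_chi2(t) == pytest.approx(expected, abs=1e-9)


def test_chi2_yates_matches_scipy():
    for t in random_tables(200, seed=43):
        expected = stats.chi2_contingency(
            [[t.a, t.b], [t.c, t.d]], correction=True
        ).statistic
        assert pearson_chi2(t, yates=True) == pytest.approx(expected, abs=1e-9)


def test_chi2_zero_for_identical_proportions():
    assert pearson_chi2(TwoByTwo(10, 90, 20, 180)) == pytest.approx(0.0, abs=1e-12)


def test_chi2_invariant_under_group_swap():
    for t in random_tables(50, seed=44):
        assert pearson_chi2(t) == pytest.approx(pearson_chi2(t.swap_groups()), rel=1e-12)


def test_chi2_zero_margin_rejected():
    with pytest.raises(UndefinedStatisticError):
        pearson_chi2(TwoByTwo(0, 10, 0, 20))


# --------------------------------------------------------------- Fisher exact


def enumerate_fisher(a, b, c, d):
    """Independent oracle: full hypergeometric enumeration over the support,
    minimum-likelihood two-sided convention."""
    n, k_row, k_col = a + b + c + d, a + b, a + c
    support = range(max(0, k_row + k_col - n), min(k_row, k_col) + 1)
    pmf = {x: stats.hypergeom.pmf(x, n, k_row, k_col) for x in support}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9))


@pytest.mark.parametrize(
    "cells",
    [(1, 1, 1, 1), (2, 180, 0, 700), (5, 0, 0, 5), (21, 161, 37, 663), (3, 7, 9, 2)],
)
def test_fisher_matches_enumeration_oracle(cells):
    assert fisher_two_sided(TwoByTwo(*cells)) == pytest.approx(
        enumerate_fisher(*cells), rel=1e-9
    )


def test_fisher_closed_forms():
    assert fisher_two_sided(TwoByTwo(1, 1, 1, 1)) == pytest.approx(1.0)
    assert fisher_two_sided(TwoByTwo(5, 0, 0, 5)) == pytest.approx(2 / math.comb(10, 5))


def test_fisher_rejects_adjusted_tables():
    with pytest.raises(ValueError):
        fisher_two_sided(TwoByTwo(0.5, 1.5, 2.5, 3.5))


# ------------------------------------------------------------------ Woolf OR


@pytest.mark.parametrize(
    "cells, or_exp, lo_exp, hi_exp",
    [
        ((21, 161, 37, 663), 2.337, 1.332, 4.102),
        ((28.5, 152.5, 0.5, 700.5), 261.826, 15.897, 4312.308),
        ((33, 147, 6, 694), 25.966, 10.686, 63.097),
    ],
)
def test_woolf_reference_values(cells, or_exp, lo_exp, hi_exp):
    or_point, lo, hi = odds_ratio_woolf(TwoByTwo(*cells))
    assert or_point == pytest.approx(or_exp, abs=1e-3)
    assert lo == pytest.approx(lo_exp, abs=1e-3)
    assert hi == pytest.approx(hi_exp, rel=1e-4)


def test_woolf_symmetric_table_gives_unit_or():
    for k in (1, 5, 100):
        or_point, lo, hi = odds_ratio_woolf(TwoByTwo(k, k, k, k))
        assert or_point == pytest.approx(1.0)
        assert lo < 1.0 < hi


def test_group_swap_inverts_or():
    for t in random_tables(50, seed=45):
        or1, lo1, hi1 = odds_ratio_woolf(t)
        or2, lo2, hi2 = odds_ratio_woolf(t.swap_groups())
        assert or2 == pytest.approx(1 / or1, rel=1e-12)
        assert lo2 == pytest.approx(1 / hi1, rel=1e-12)


def test_woolf_requires_positive_cells():
    with pytest.raises(UndefinedStatisticError):
        odds_ratio_woolf(TwoByTwo(0, 5, 5, 5))


# ------------------------------------------------------- locus-wise correction


@pytest.mark.parametrize(
    "p, n, expected",
    [(0.002, 31, 0.060), (0.25, 1, 0.25), (0.001, 14, 0.01391)],
)
def test_locus_correct_values(p, n, expected):
    assert locus_correct(p, n) == pytest.approx(expected, abs=5e-4)


def test_locus_correct_monotone_and_bounded():
    grid = np.linspace(0, 1, 21)
    for n in (1, 2, 14, 31):
        pcs = [locus_correct(p, n) for p in grid]
        assert all(0 <= pc <= 1 for pc in pcs)
        assert all(pc >= p - 1e-12 for pc, p in zip(pcs, grid))
        assert all(b >= a for a, b in zip(pcs, pcs[1:]))
    # monotone in n too
    assert locus_correct(0.01, 5) <= locus_correct(0.01, 10)


def test_locus_correct_no_underflow():
    tiny = 1e-200
    assert locus_correct(tiny, 31) == pytest.approx(31 * tiny, rel=1e-6)


# ------------------------------------------------------------- Haberman ASR


def table_from_matrix(observed):
    rows = {
        parse_allele(f"A*{i + 1:02d}"): (int(o[0]), int(o[1]))
        for i, o in enumerate(observed)
    }
    case_2n = int(sum(o[0] for o in observed))
    ctrl_2n = int(sum(o[1] for o in observed))
    return AlleleCountTable("A", rows, case_2n, ctrl_2n)


def test_asr_hand_computed_example():
    res = haberman_asr(table_from_matrix([[30, 70], [10, 90]]))
    assert res.asr[0, 0] == pytest.approx((30 - 20) / math.sqrt(20 * 0.5 * 0.8), abs=1e-9)
    assert res.asr[0, 0] == pytest.approx(3.536, abs=1e-3)


def test_asr_zero_when_observed_equals_expected():
    res = haberman_asr(table_from_matrix([[20, 40], [30, 60]]))
    assert np.allclose(res.asr, 0.0, atol=1e-9)


def test_asr_margins_and_antisymmetry():
    rng = np.random.default_rng(7)
    for _ in range(20):
        observed = rng.integers(1, 100, size=(4, 2))
        res = haberman_asr(table_from_matrix(observed))
        diff = res.observed - res.expected
        assert np.allclose(diff.sum(axis=0), 0, atol=1e-9)
        assert np.allclose(diff.sum(axis=1), 0, atol=1e-9)
        # in a two-column table the case and control residuals mirror
        assert np.allclose(res.asr[:, 0], -res.asr[:, 1], atol=1e-9)


def test_asr_formula_oracle_on_random_tables():
    rng = np.random.default_rng(8)
    for _ in range(50):
        observed = rng.integers(1, 80, size=(5, 2)).astype(float)
        res = haberman_asr(table_from_matrix(observed))
        grand = observed.sum()
        for i in range(5):
            for j in range(2):
                e = observed[i].sum() * observed[:, j].sum() / grand
                asr = (observed[i, j] - e) / math.sqrt(
                    e * (1 - observed[i].sum() / grand) * (1 - observed[:, j].sum() / grand)
                )
                assert res.asr[i, j] == pytest.approx(asr, abs=1e-9)


# ------------------------------------------------------------------ run_locus


def test_run_locus_row_counts_match_allele_counts(fixtures):
    assert len(run_locus(fixtures["B"])) == 31
    assert len(run_locus(fixtures["A"])) == 18


def test_run_locus_sorted_by_chi2_and_carries_flags(fixtures):
    rows = run_locus(fixtures["DQA1"])
    chi2s = [r.chi2 for r in rows]
    assert chi2s == sorted(chi2s, reverse=True)
    top = rows[0]
    assert str(top.allele) == "DQA1*05:05:01"
    assert top.zero_cell_adjusted
    assert top.n_alleles_locus == 14
    assert top.ci_low <= top.or_point <= top.ci_high
    assert top.asr > 1.96  # flagged contributor


def test_run_locus_rejects_degenerate_locus():
    single = AlleleCountTable("A", {parse_allele("A*01"): (5, 5)}, 10, 10)
    with pytest.raises((UndefinedStatisticError, ValueError)):
        run_locus(single)


def test_assoc_row_validates_ci():
    with pytest.raises(ValueError):
        AssocRow("x", 0.1, 0.1, 1.0, 0.3, None, 2.0, 2.5, 3.0, 0.5, None, 2, False)
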