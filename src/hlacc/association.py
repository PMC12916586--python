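"""Per-allele 2x2 association statistics for case-control allele counts.

For each allele at a locus the 2x2 table is

              carrier  non-carrier
    cases        a          b          (a + b = case 2N)
    controls     c          d          (c + d = control 2N)

on chromosomes.  Highly polymorphic loci in a rare disease routinely
produce zero cells (an allele seen in only one group); those tables get
the Haldane-Anscombe treatment (add 0.5 to every cell) before the Pearson
chi-square and the Woolf log-OR interval, which keeps both finite while
leaving non-sparse tables untouched.  Fisher's exact test (minimum-
likelihood two-sided convention) is always computed on the raw integer
table.  Multiplicity within a locus is handled by the Sidak-type
correction pc = 1 - (1 - p)^n over the n alleles tested at that locus,
and Haberman adjusted standardized residuals localize which alleles drive
a table-wide signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .io import AlleleCountTable
from .nomenclature import AlleleName

Z_95 = 1.959963984540054  # two-sided 95% normal quantile
ASR_SIGNIFICANT = 1.96


class UndefinedStatisticError(ValueError):
    """A margin of the 2x2 table is zero; the statistic does not exist."""


@dataclass(frozen=True)
class TwoByTwo:
    """A chromosome-level 2x2 table; cells may be 0.5-adjusted reals."""

    a: float  # case carriers
    b: float  # case non-carriers
    c: float  # control carriers
    d: float  # control non-carriers
    zero_cell_adjusted: bool = False

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell in 2x2 table")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def swap_groups(self) -> "TwoByTwo":
        return TwoByTwo(self.c, self.d, self.a, self.b, self.zero_cell_adjusted)


@dataclass(frozen=True)
class AssocRow:
    """One allele's (or haplotype's) full statistics row."""

    allele: object
    freq_case: float
    freq_control: float
    chi2: float
    p_chi2: float
    p_fisher: float | None
    or_point: float
    ci_low: float
    ci_high: float
    p_corrected: float
    asr: float | None
    n_alleles_locus: int
    zero_cell_adjusted: bool
    em_unstable: bool = False

    def __post_init__(self) -> None:
        if not self.ci_low <= self.or_point <= self.ci_high:
            raise ValueError("CI does not bracket the odds ratio")


@dataclass
class ResidualTable:
    """Observed/expected counts and Haberman residuals for one locus."""

    locus: str
    alleles: list[AlleleName]
    observed: np.ndarray  # (n_alleles, 2): case, control columns
    expected: np.ndarray
    asr: np.ndarray

    @property
    def significant(self) -> np.ndarray:
        return np.abs(self.asr) >= ASR_SIGNIFICANT


def build_2x2(counts: AlleleCountTable, allele: AlleleName) -> TwoByTwo:
    """Carrier/non-carrier chromosome table for one allele."""
    if allele not in counts.rows:
        raise KeyError(f"{allele} not in {counts.locus} count table")
    a, c = counts.rows[allele]
    return TwoByTwo(a, counts.case_total_2n - a, c, counts.control_total_2n - c)


def haldane_adjust(t: TwoByTwo) -> TwoByTwo:
    """Add 0.5 to every cell iff the table contains an exact zero."""
    if min(t.a, t.b, t.c, t.d) == 0:
        return TwoByTwo(t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5, True)
    return t


def pearson_chi2(t: TwoByTwo, yates: bool = False) -> float:
    """Pearson chi-square on a (possibly 0.5-adjusted) 2x2 table.

    With ``yates`` the continuity correction subtracts N/2 from |ad - bc|
    (floored at zero).  Raises if any margin is zero.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise UndefinedStatisticError("zero margin: chi-square undefined")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    return n * diff * diff / margins


def chi2_pvalue(chi2: float) -> float:
    """Upper-tail p for a 1-df chi-square statistic."""
    return float(stats.chi2.sf(chi2, df=1))


def fisher_two_sided(t: TwoByTwo) -> float:
    """Two-sided Fisher exact p (minimum-likelihood convention).

    Sums hypergeometric probabilities of every table with the observed
    margins whose point probability does not exceed the observed table's.
    Requires the raw integer table (apply before any 0.5 adjustment).
    """
    cells = (t.a, t.b, t.c, t.d)
    if any(not float(x).is_integer() for x in cells):
        raise ValueError("Fisher's exact test needs integer cell counts")
    a, b, c, d = (int(x) for x in cells)
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def odds_ratio_woolf(t: TwoByTwo) -> tuple[float, float, float]:
    """Odds ratio with the Woolf 95% CI: exp(ln OR +/- 1.96 sqrt(sum 1/cell)).

    All four cells must be positive (use :func:`haldane_adjust` first for
    sparse tables).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) <= 0:
        raise UndefinedStatisticError("zero cell: apply the Haldane adjustment first")
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (
        math.exp(log_or),
        math.exp(log_or - Z_95 * se),
        math.exp(log_or + Z_95 * se),
    )


def locus_correct(p: float, n_alleles: int) -> float:
    """Sidak-type locus-wise correction pc = 1 - (1 - p)^n.

    Evaluated in log space (``-expm1(n * log1p(-p))``) so that corrected
    p-values stay accurate far below 1e-12.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0, 1]")
    if n_alleles < 1:
        raise ValueError("n_alleles must be >= 1")
    if p == 1.0:
        return 1.0
    pc = -math.expm1(n_alleles * math.log1p(-p))
    return min(max(pc, 0.0), 1.0)


def haberman_asr(counts: AlleleCountTable) -> ResidualTable:
    """Haberman adjusted standardized residuals for the alleles x groups table.

    ASR_ij = (O_ij - E_ij) / sqrt(E_ij (1 - rowprop_i)(1 - colprop_j)) with
    E the usual independence expectation; approximately N(0,1) under the
    null, so |ASR| >= 1.96 flags alleles driving the locus-wide signal.
    """
    alleles = list(counts.rows)
    if len(alleles) < 2:
        raise ValueError("need >= 2 alleles for residual analysis")
    observed = np.array([counts.rows[a] for a in alleles], dtype=float)
    rowtot = observed.sum(axis=1)
    coltot = observed.sum(axis=0)
    grand = observed.sum()
    if grand == 0 or (coltot == 0).any():
        raise ValueError("zero group total")
    expected = np.outer(rowtot, coltot) / grand
    denom = np.sqrt(
        expected
        * (1.0 - rowtot / grand)[:, None]
        * (1.0 - coltot / grand)[None, :]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        asr = np.where(denom > 0, (observed - expected) / denom, 0.0)
    return ResidualTable(counts.locus, alleles, observed, expected, asr)


def run_locus(counts: AlleleCountTable, yates: bool = False) -> list[AssocRow]:
    """All per-allele statistics for one locus, sorted by descending chi2.

    The chi-square (and the Woolf OR/CI) are computed on the Haldane-
    adjusted table when a zero cell is present; Fisher's exact p always
    uses the raw integer counts.  The locus-wise corrected p applies the
    Sidak-type formula with n = number of alleles in the table.
    """
    if counts.n_alleles < 2:
        raise UndefinedStatisticError("single-allele locus: chi-square undefined")
    residuals = haberman_asr(counts)
    asr_case = {a: float(residuals.asr[i, 0]) for i, a in enumerate(residuals.alleles)}
    n = counts.n_alleles
    rows = []
    for allele in counts.rows:
        raw = build_2x2(counts, allele)
        adj = haldane_adjust(raw)
        chi2 = pearson_chi2(adj, yates=yates)
        p = chi2_pvalue(chi2)
        or_point, ci_low, ci_high = odds_ratio_woolf(adj)
        rows.append(
            AssocRow(
                allele=allele,
                freq_case=counts.freq_case(allele),
                freq_control=counts.freq_control(allele),
                chi2=chi2,
                p_chi2=p,
                p_fisher=fisher_two_sided(raw),
                or_point=or_point,
                ci_low=ci_low,
                ci_high=ci_high,
                p_corrected=locus_correct(p, n),
                asr=asr_case[allele],
                n_alleles_locus=n,
                zero_cell_adjusted=adj.zero_cell_adjusted,
            )
        )
    rows.sort(key=lambda r: (-r.chi2, str(r.allele)))
    return rows
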