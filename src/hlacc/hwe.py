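"""Monte-Carlo exact Hardy-Weinberg equilibrium test for multi-allelic loci.

Deviation from HWE in a control cohort can flag genotyping error, allele
dropout, or cryptic population stratification (the Wahlund effect, which
depresses heterozygosity when subpopulations with divergent allele
frequencies are pooled).  For HLA loci with dozens of alleles the
asymptotic chi-square test is useless, so the test here is exact and
conditional: given the observed allele counts, the probability of a
genotype configuration {n_gt} among n individuals is

    P = n! * prod_a(count_a!) * 2^h / ((2n)! * prod_gt(n_gt!))

with h the number of heterozygotes.  The p-value is the probability mass
of configurations no more probable than the observed one, estimated by
randomly re-pairing the pooled allele vector (Monte-Carlo permutation of
gametes), with the +1/+1 estimator so p is never zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .io import CohortTable

_LOG2 = math.log(2.0)
_TIE_TOL = 1e-9  # float tolerance when comparing replicate stats to observed


@dataclass
class GenotypeCountTable:
    """Unordered genotype (allele-pair) counts at one locus."""

    locus: str
    counts: dict[tuple[str, str], int]
    n_individuals: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_individuals:
            raise ValueError("genotype counts do not sum to n_individuals")
        for (x, y), k in self.counts.items():
            if (x, y) != tuple(sorted((x, y))):
                raise ValueError(f"genotype key {(x, y)} not sorted")
            if k < 0:
                raise ValueError("negative genotype count")

    @property
    def allele_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (x, y), k in self.counts.items():
            out[x] = out.get(x, 0) + k
            out[y] = out.get(y, 0) + k
        return out


@dataclass(frozen=True)
class HWEResult:
    locus: str
    p_value: float
    n_replicates: int
    seed: int | None
    observed_stat: float  # log conditional probability of the observed table
    n_individuals: int
    n_alleles: int


def genotype_counts(cohort: CohortTable, locus: str) -> GenotypeCountTable:
    """Tally unordered genotype pairs at *locus* (order-invariant)."""
    counts: dict[tuple[str, str], int] = {}
    n = 0
    for rec in cohort.records:
        pair = rec.genotype.get(locus)
        if pair is None:
            continue
        key = tuple(sorted((str(pair[0]), str(pair[1]))))
        counts[key] = counts.get(key, 0) + 1
        n += 1
    if n == 0:
        raise ValueError(f"locus {locus} untyped in cohort")
    return GenotypeCountTable(locus, counts, n)


def _log_conditional_prob(g: GenotypeCountTable) -> float:
    n = g.n_individuals
    allele_counts = list(g.allele_counts.values())
    h = sum(k for (x, y), k in g.counts.items() if x != y)
    return float(
        gammaln(n + 1)
        + sum(gammaln(k + 1) for k in allele_counts)
        + h * _LOG2
        - gammaln(2 * n + 1)
        - sum(gammaln(k + 1) for k in g.counts.values())
    )


def _replicate_stats(pool: np.ndarray, k: int, n_rep: int, rng: np.random.Generator) -> np.ndarray:
    """Log conditional probability of *n_rep* random gamete re-pairings.

    The constant terms (n!, allele-count factorials, (2n)!) cancel in the
    comparison with the observed statistic, but are included so replicate
    stats are on the same scale as :func:`_log_conditional_prob`.
    """
    n = pool.size // 2
    const = (
        gammaln(n + 1)
        + gammaln(np.bincount(pool, minlength=k) + 1).sum()
        - gammaln(2 * n + 1)
    )
    perms = np.tile(pool, (n_rep, 1))
    perms = rng.permuted(perms, axis=1)
    a, b = perms[:, ::2], perms[:, 1::2]
    codes = np.minimum(a, b) * k + np.maximum(a, b)
    counts = np.zeros((n_rep, k * k))
    np.add.at(
        counts,
        (np.repeat(np.arange(n_rep), n), codes.ravel()),
        1.0,
    )
    h = (a != b).sum(axis=1)
    return const + h * _LOG2 - gammaln(counts + 1).sum(axis=1)


def hwe_exact_mc(
    g: GenotypeCountTable,
    n_replicates: int = 10_000,
    seed: int | None = None,
    chunk: int = 2_000,
) -> HWEResult:
    """Monte-Carlo exact HWE test conditional on allele counts.

    p = (1 + #{replicates with log-probability <= observed}) / (R + 1),
    deterministic for a fixed *seed*.  A monomorphic locus returns p = 1
    with a warning (no test is possible).
    """
    alleles = sorted(g.allele_counts)
    k = len(alleles)
    observed = _log_conditional_prob(g)
    if k < 2:
        warnings.warn(f"{g.locus}: monomorphic locus, HWE test undefined; p = 1")
        return HWEResult(g.locus, 1.0, 0, seed, observed, g.n_individuals, k)
    if g.n_individuals < 2:
        raise ValueError("need >= 2 individuals")

    index = {a: i for i, a in enumerate(alleles)}
    pool = np.empty(2 * g.n_individuals, dtype=np.int64)
    pos = 0
    for (x, y), count in sorted(g.counts.items()):
        for _ in range(count):
            pool[pos] = index[x]
            pool[pos + 1] = index[y]
            pos += 2

    rng = np.random.default_rng(seed)
    n_le = 0
    done = 0
    while done < n_replicates:
        m = min(chunk, n_replicates - done)
        stats = _replicate_stats(pool, k, m, rng)
        n_le += int((stats <= observed + _TIE_TOL).sum())
        done += m
    p = (1 + n_le) / (n_replicates + 1)
    return HWEResult(g.locus, p, n_replicates, seed, observed, g.n_individuals, k)


def hwe_exact_biallelic(g: GenotypeCountTable) -> float:
    """Exact HWE p for a two-allele locus by full enumeration.

    Sums the conditional distribution over every heterozygote count with
    the parity of the minor-allele count; the limit the Monte-Carlo
    estimate converges to as replicates grow.  Useful as an independent
    check of the sampler.
    """
    allele_counts = g.allele_counts
    if len(allele_counts) == 1:
        return 1.0
    if len(allele_counts) != 2:
        raise ValueError("exact enumeration implemented for two alleles only")
    n = g.n_individuals
    n_minor = min(allele_counts.values())
    h_obs = sum(k for (x, y), k in g.counts.items() if x != y)

    def log_prob(h: int) -> float:
        n_aa = (n_minor - h) // 2  # minor homozygotes
        n_bb = n - n_aa - h
        return (
            gammaln(n + 1)
            + sum(gammaln(k + 1) for k in allele_counts.values())
            + h * _LOG2
            - gammaln(2 * n + 1)
            - gammaln(n_aa + 1)
            - gammaln(h + 1)
            - gammaln(n_bb + 1)
        )

    support = range(n_minor % 2, n_minor + 1, 2)
    logs = {h: log_prob(h) for h in support}
    target = logs[h_obs]
    total = np.logaddexp.reduce(list(logs.values()))
    keep = [lp for lp in logs.values() if lp <= target + _TIE_TOL]
    return float(math.exp(np.logaddexp.reduce(keep) - total))
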