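"""EM haplotype-frequency estimation and multi-allelic linkage disequilibrium.

Unphased multi-locus genotypes are compatible with up to 2^(h-1)
haplotype-pair resolutions (h = number of heterozygous loci).  The
gene-counting EM distributes each individual's unit of mass over its
phase-consistent pairs in proportion to the current pair probabilities
(2 f_i f_j for distinct haplotypes, f_i^2 for a homozygous pair), then
re-estimates frequencies from the expected haplotype counts — the
classical maximum-likelihood approach for population haplotype
frequencies.  The log-likelihood is non-decreasing every iteration, a
property asserted at runtime.

Pairwise LD between two multi-allelic loci is summarized from the
two-locus haplotype frequencies: for each allele pair, D_ij = p_ij -
p_i q_j, normalized to D' by its frequency-bound maximum, and
r^2_ij = D_ij^2 / (p_i(1-p_i) q_j(1-q_j)); the locus-pair summary is the
frequency-weighted (default) or unweighted mean of |D'| and r^2 across
allelic combinations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .association import (
    AssocRow,
    TwoByTwo,
    chi2_pvalue,
    haldane_adjust,
    locus_correct,
    odds_ratio_woolf,
    pearson_chi2,
)
from .io import CohortTable
from .nomenclature import LOCI

Haplotype = tuple[str, ...]

MAX_HET_LOCI = 20  # 2^(h-1) phase expansion guard


@dataclass
class HaplotypeFreqTable:
    """EM-estimated haplotype frequencies over an ordered locus subset."""

    loci: tuple[str, ...]
    freqs: dict[Haplotype, float]
    loglik: float
    loglik_trace: list[float]
    n_iter: int
    converged: bool
    n_records: int

    @property
    def n_chromosomes(self) -> int:
        return 2 * self.n_records

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if self.freqs and abs(total - 1.0) > 1e-6:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")


@dataclass
class LDMatrix:
    """Symmetric mean |D'| and mean r^2 matrices over a locus list."""

    loci: tuple[str, ...]
    dprime: np.ndarray
    rsq: np.ndarray

    def __post_init__(self) -> None:
        for m in (self.dprime, self.rsq):
            if m.shape != (len(self.loci), len(self.loci)):
                raise ValueError("matrix shape does not match loci")


def _phase_pairs(genotype: tuple[tuple[str, str], ...]) -> list[tuple[Haplotype, Haplotype]]:
    """All phase-consistent haplotype pairs for one unphased genotype.

    The first heterozygous locus is pinned to break the mirror symmetry,
    giving 2^(h-1) distinct unordered pairs.
    """
    het = [i for i, (x, y) in enumerate(genotype) if x != y]
    if not het:
        hap = tuple(x for x, _ in genotype)
        return [(hap, hap)]
    pairs = []
    for bits in itertools.product((0, 1), repeat=len(het) - 1):
        h1, h2 = list(list(x for x, _ in genotype) for _ in range(2))
        flips = (0,) + bits
        for locus_idx, flip in zip(het, flips):
            x, y = genotype[locus_idx]
            h1[locus_idx], h2[locus_idx] = (x, y) if flip == 0 else (y, x)
        pairs.append((tuple(h1), tuple(h2)))
    return pairs


def _collapse_records(cohort: CohortTable, loci: tuple[str, ...]):
    """Unique complete genotypes with multiplicities (records missing any
    requested locus are excluded)."""
    seen: dict[tuple, int] = {}
    for rec in cohort.records:
        pairs = []
        for locus in loci:
            g = rec.genotype.get(locus)
            if g is None:
                break
            pairs.append(tuple(sorted((str(g[0]), str(g[1])))))
        else:
            key = tuple(pairs)
            seen[key] = seen.get(key, 0) + 1
    return seen


def em_haplotypes(
    cohort: CohortTable,
    loci: tuple[str, ...] | list[str],
    tol: float = 1e-8,
    max_iter: int = 1000,
    init: str = "allele-freq",
) -> HaplotypeFreqTable:
    """Maximum-likelihood haplotype frequencies by gene-counting EM.

    ``init='allele-freq'`` starts from the product of observed allele
    frequencies, which deterministically breaks the symmetric double-
    heterozygote ties; ``init='uniform'`` is available for likelihood-
    surface checks.  Convergence is declared when the relative
    log-likelihood change drops below *tol*; haplotypes below 1e-10 are
    pruned on completion.
    """
    loci = tuple(loci)
    if len(loci) > 7:
        raise ValueError("at most 7 loci supported")
    genotypes = _collapse_records(cohort, loci)
    if not genotypes:
        raise ValueError("no records complete at the requested loci")

    expansions: list[tuple[int, list[tuple[int, int]]]] = []
    hap_index: dict[Haplotype, int] = {}

    def idx(h: Haplotype) -> int:
        if h not in hap_index:
            hap_index[h] = len(hap_index)
        return hap_index[h]

    for genotype, mult in genotypes.items():
        n_het = sum(1 for x, y in genotype if x != y)
        if n_het > MAX_HET_LOCI:
            raise ValueError(f"genotype heterozygous at {n_het} loci: expansion too large")
        pairs = [(idx(h1), idx(h2)) for h1, h2 in _phase_pairs(genotype)]
        expansions.append((mult, pairs))

    haps = [h for h, _ in sorted(hap_index.items(), key=lambda kv: kv[1])]
    n_hap = len(haps)
    n_records = sum(genotypes.values())

    if init == "uniform":
        freqs = np.full(n_hap, 1.0 / n_hap)
    elif init == "allele-freq":
        # product of per-locus observed allele frequencies, renormalized
        allele_freq: list[dict[str, float]] = []
        for j, locus in enumerate(loci):
            counts: dict[str, float] = {}
            for genotype, mult in genotypes.items():
                for a in genotype[j]:
                    counts[a] = counts.get(a, 0.0) + mult
            total = sum(counts.values())
            allele_freq.append({a: c / total for a, c in counts.items()})
        freqs = np.array(
            [math.prod(allele_freq[j][h[j]] for j in range(len(loci))) for h in haps]
        )
        freqs /= freqs.sum()
    else:
        raise ValueError(f"unknown init {init!r}")
    # deterministic tie-break: exactly symmetric phase configurations (e.g. a
    # lone double heterozygote) put both inits on a saddle of the likelihood;
    # a tiny index-ordered perturbation lets EM descend to one optimum,
    # reproducibly, without randomness
    freqs = freqs * (1.0 + 1e-3 * np.arange(n_hap) / max(n_hap - 1, 1))
    freqs /= freqs.sum()

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        expected = np.zeros(n_hap)
        loglik = 0.0
        for mult, pairs in expansions:
            weights = np.array(
                [
                    freqs[i] * freqs[j] if i == j else 2.0 * freqs[i] * freqs[j]
                    for i, j in pairs
                ]
            )
            total = weights.sum()
            if total <= 0:
                # genotype unexplainable under current freqs; restart flat
                weights = np.full(len(pairs), 1.0 / len(pairs))
                total = 1.0
                loglik += mult * -700.0
            else:
                weights = weights / total
                loglik += mult * math.log(total)
            for (i, j), w in zip(pairs, weights):
                expected[i] += mult * w
                expected[j] += mult * w
        freqs = expected / (2 * n_records)
        if trace and loglik < trace[-1] - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        done = bool(trace) and abs(loglik - trace[-1]) <= tol * max(1.0, abs(loglik))
        trace.append(loglik)
        if done:
            converged = True
            break

    out = {
        h: float(f) for h, f in zip(haps, freqs) if f >= 1e-10
    }
    return HaplotypeFreqTable(loci, out, trace[-1], trace, it, converged, n_records)


def ld_pair(freq2: HaplotypeFreqTable, weighting: str = "frequency") -> tuple[float, float]:
    """Mean |D'| and mean r^2 for a two-locus haplotype frequency table.

    ``weighting='frequency'`` weights each allelic combination by
    p_i q_j (the standard multi-allelic summary); ``'uniform'`` takes the
    plain mean.  A monomorphic locus has no defined LD and yields NaN.
    """
    if len(freq2.loci) != 2:
        raise ValueError("ld_pair needs a 2-locus frequency table")
    if weighting not in ("frequency", "uniform"):
        raise ValueError(f"unknown weighting {weighting!r}")
    p: dict[str, float] = {}
    q: dict[str, float] = {}
    for (x, y), f in freq2.freqs.items():
        p[x] = p.get(x, 0.0) + f
        q[y] = q.get(y, 0.0) + f
    if len(p) < 2 or len(q) < 2:
        return (math.nan, math.nan)

    dp_num = rs_num = w_total = 0.0
    for xi, pi in p.items():
        for yj, qj in q.items():
            pij = freq2.freqs.get((xi, yj), 0.0)
            d = pij - pi * qj
            if d >= 0:
                d_max = min(pi * (1 - qj), (1 - pi) * qj)
            else:
                d_max = min(pi * qj, (1 - pi) * (1 - qj))
            dprime = abs(d) / d_max if d_max > 0 else 0.0
            denom = pi * (1 - pi) * qj * (1 - qj)
            rsq = d * d / denom if denom > 0 else 0.0
            w = pi * qj if weighting == "frequency" else 1.0
            dp_num += w * dprime
            rs_num += w * rsq
            w_total += w
    return (dp_num / w_total, rs_num / w_total)


def ld_matrix(
    cohort: CohortTable,
    loci: tuple[str, ...] | list[str] | None = None,
    weighting: str = "frequency",
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> LDMatrix:
    """Pairwise mean |D'| and r^2 matrices via two-locus EM per pair.

    Loci default to all typed loci in chromosomal order (A, C, B, DRB1,
    DQA1, DQB1, DPB1); the diagonal is 1 by convention.
    """
    if loci is None:
        loci = tuple(l for l in LOCI if l in cohort.loci)
    loci = tuple(loci)
    if len(loci) < 2:
        raise ValueError("need >= 2 loci for an LD matrix")
    k = len(loci)
    dprime = np.eye(k)
    rsq = np.eye(k)
    for i, j in itertools.combinations(range(k), 2):
        freq2 = em_haplotypes(cohort, (loci[i], loci[j]), tol=tol, max_iter=max_iter)
        dp, rs = ld_pair(freq2, weighting=weighting)
        dprime[i, j] = dprime[j, i] = dp
        rsq[i, j] = rsq[j, i] = rs
    return LDMatrix(loci, dprime, rsq)


def haplotype_assoc(
    case_freqs: HaplotypeFreqTable,
    control_freqs: HaplotypeFreqTable,
    case_2n: int | None = None,
    control_2n: int | None = None,
) -> list[AssocRow]:
    """Case-control association of EM-estimated haplotypes.

    Expected chromosome counts (frequency x 2N, fractional) feed the same
    Haldane/chi-square/Woolf machinery as single alleles, with the
    Sidak-type correction over the number of haplotypes tested.  Rows
    involving any haplotype estimated below 5 chromosomes are flagged
    ``em_unstable``: zero- and near-zero-frequency cells destabilize
    maximum-likelihood haplotype estimation, so such tests are
    approximate (phase uncertainty is not propagated).
    """
    if case_freqs.loci != control_freqs.loci:
        raise ValueError("haplotype tables cover different loci")
    case_2n = case_2n or case_freqs.n_chromosomes
    control_2n = control_2n or control_freqs.n_chromosomes
    haps = sorted(set(case_freqs.freqs) | set(control_freqs.freqs))
    n = len(haps)
    rows = []
    for hap in haps:
        f_case = case_freqs.freqs.get(hap, 0.0)
        f_ctrl = control_freqs.freqs.get(hap, 0.0)
        a = f_case * case_2n
        c = f_ctrl * control_2n
        t = haldane_adjust(TwoByTwo(a, case_2n - a, c, control_2n - c))
        chi2 = pearson_chi2(t)
        p = chi2_pvalue(chi2)
        or_point, ci_low, ci_high = odds_ratio_woolf(t)
        unstable = a < 5.0 or c < 5.0
        rows.append(
            AssocRow(
                allele="~".join(hap),
                freq_case=f_case,
                freq_control=f_ctrl,
                chi2=chi2,
                p_chi2=p,
                p_fisher=None,
                or_point=or_point,
                ci_low=ci_low,
                ci_high=ci_high,
                p_corrected=locus_correct(p, n),
                asr=None,
                n_alleles_locus=n,
                zero_cell_adjusted=t.zero_cell_adjusted,
                em_unstable=unstable,
            )
        )
    rows.sort(key=lambda r: (-r.chi2, str(r.allele)))
    return rows
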