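# Methods

## Setting and data model

The unit of analysis is the chromosome. At each HLA locus, every
individual typed there contributes two allele calls (homozygotes repeat
the call), so a group of N individuals yields 2N chromosomes and each
allele's frequency is its chromosome count divided by 2N (gene counting).
Missingness is handled locus-wise: an individual untyped at DRB1 still
contributes at every other locus, which is why per-locus denominators are
always derived from the data rather than from the nominal sample size.
The built-in reference tables illustrate the point: the case group has
182 chromosomes at five loci but 180 at DRB1/DQA1, and the control
denominators are uniformly 700.

Alleles are compared as exact strings at their given resolution,
including the expression suffix (`B*39:01:01L ≠ B*39:01:01`). No implicit
roll-up to two-field names is ever performed, because three-field
("six-digit") siblings such as `DPB1*02:01:01` and `DPB1*02:01:02` can
carry opposite disease associations; an explicit `AlleleName.truncate`
is provided for users who want coarser grouping.

## Per-allele association

Each allele is tested against all other alleles pooled, as a 2×2
carrier/non-carrier chromosome table (a, b; c, d) with fixed group
margins.

**Zero cells.** A rare disease plus highly polymorphic loci guarantees
alleles observed in only one group. Such tables receive the
Haldane–Anscombe correction — 0.5 added to all four cells — *before* the
Pearson χ² and the Woolf interval; non-sparse tables are left untouched.
This is an explicit, flagged table transform (`zero_cell_adjusted` is
carried through to output), not a silent fallback. Fisher's exact test is
always computed on the raw integer table and needs no correction.

**χ².** The plain Pearson statistic
`N(ad − bc)² / ((a+b)(c+d)(a+c)(b+d))`, accepting the non-integer
0.5-adjusted cells. A Yates-corrected variant (δ = N/2 subtracted from
|ad − bc|) is available behind a flag but is off by default: the
uncorrected statistic is the one that matches the reference values this
package reproduces, including for sparse tables.

**Odds ratio.** OR = ad/(bc) with the Woolf (log-normal) 95% interval
`exp(ln OR ± z·SE)`, `SE = √(1/a + 1/b + 1/c + 1/d)`, z = 1.959964. On
the Haldane-adjusted table this yields finite, very large ORs with
appropriately wide intervals for case-exclusive alleles (e.g. 28 vs 0
carriers → OR ≈ 262 with CI spanning two orders of magnitude) — the
interval width, not the point estimate, is the honest summary there.

**Fisher's exact test.** Two-sided by the minimum-likelihood convention:
the sum of hypergeometric probabilities, over all tables with the
observed margins, that do not exceed the observed table's probability.
The implementation delegates to `scipy.stats.fisher_exact` (which uses
exactly this convention); the test suite checks it against an independent
full enumeration of the hypergeometric support.

**Multiplicity.** Within a locus, `p_c = 1 − (1 − p)^n` with n the number
of alleles tested there — a Šidák-type transform, computed in log space
as `-expm1(n·log1p(−p))` so corrected values remain accurate for p far
below 1e-12. It is monotone in both arguments and bounded by [p, 1]; no
sum-type (Bonferroni) bound is implied.

**Residuals.** Haberman adjusted standardized residuals over the full
alleles × groups count table:
`ASR_ij = (O_ij − E_ij)/√(E_ij (1 − rowtot_i/T)(1 − coltot_j/T))`.
Under independence each cell is approximately N(0, 1); with two group
columns the case and control residuals of an allele mirror each other
exactly. The test suite verifies ~5% exceedance of |ASR| ≥ 1.96 under a
multinomial null with expected cell counts ≥ 50.

The crude p reported for each allele is the χ²-derived upper-tail
probability; the Fisher p is reported in its own column rather than
being swapped in for sparse tables, so every row states which statistic
produced which number. Output rows are ordered by descending χ² with a
stable tie-break on allele name.

## Hardy–Weinberg testing

For multi-allelic loci the test is exact and conditional on the observed
allele counts. The statistic is the log conditional probability of the
genotype configuration,

    log P = log n! + Σ_a log n_a! + h·log 2 − log (2n)! − Σ_g log n_g!

(h = number of heterozygotes), and the p-value is the probability mass of
configurations no more probable than the observed one. That mass is
estimated by Monte Carlo: the pooled 2n-allele vector is randomly
permuted and paired off (R = 10,000 replicates by default), and
p = (1 + #{stat_r ≤ stat_obs}) / (R + 1), which can never be zero and is
bit-reproducible for a fixed seed. Replicate statistics are computed
vectorized in chunks; equality in the comparison uses a 1e-9 tolerance
since the observed and replicate statistics are accumulated in different
orders. A conditional permutation scheme was chosen over parametric
resampling of genotypes from the frequency estimates because it removes
the nuisance allele frequencies exactly, the standard construction for
exact HWE tests; a monomorphic locus returns p = 1 with a warning.

For two-allele loci a closed-form enumeration over all heterozygote
counts of the correct parity (`hwe_exact_biallelic`) provides the exact
answer; the MC estimate is verified against it within Monte-Carlo error.
Simulation sizes used in the calibration checks: 1,000 random-mating
cohorts of 100 individuals at a four-allele locus (frequencies
0.4/0.3/0.2/0.1) with 2,000 replicates per cohort for the type-I error,
and 200 cohorts of a 50/50 mixture of subpopulations at 0.9/0.1 vs
0.1/0.9 for the Wahlund power check. The API default remains 10,000
replicates.

## Haplotypes and LD

**EM.** Each individual's unphased multi-locus genotype is compatible
with 2^(h−1) unordered haplotype pairs (h = heterozygous loci, capped at
20). The E-step distributes each individual's unit mass over its pairs
proportionally to 2·f_i·f_j (i ≠ j) or f_i²; the M-step sets each
frequency to its expected chromosome count over 2n. Iteration stops when
the relative log-likelihood change falls below 1e-8 (default) or at
1,000 iterations, in which case the result is returned flagged
`converged=False` rather than raising. The log-likelihood is asserted
non-decreasing at every step. Haplotypes below 1e-10 are pruned on
completion.

Initialization defaults to the product of observed allele frequencies,
with a uniform option for likelihood-surface exploration. Both inits are
exactly symmetric for a lone double heterozygote — the saddle point
between the two phase optima — so a deterministic, index-ordered
perturbation of 1e-3 relative size is applied to the initial vector.
This breaks such ties reproducibly (no randomness), and is irrelevant
away from symmetric configurations because EM re-estimates from the data
in one step.

**LD.** For two loci, with marginals p_i, q_j and joint p_ij from the
two-locus EM: D_ij = p_ij − p_i q_j, normalized to D′ by
min(p_i q_j, (1−p_i)(1−q_j)) when D < 0 and
min(p_i(1−q_j), (1−p_i)q_j) otherwise;
r²_ij = D²_ij / (p_i(1−p_i)q_j(1−q_j)). The locus-pair summary is
Σ w_ij |D′_ij| (and likewise r²) with w_ij = p_i q_j by default — the
standard multi-allelic frequency weighting — or a plain mean under
`weighting="uniform"`; "average absolute D′" is ambiguous between the
two, so both are exposed and the choice is recorded in the run manifest.
A monomorphic locus has no defined LD and reports NaN. The LD matrix is
assembled per locus pair from a fresh two-locus EM over the records
complete at that pair, with loci in chromosomal order (A, C, B, DRB1,
DQA1, DQB1, DPB1) and a unit diagonal by convention.

**Haplotype association.** EM point-estimate frequencies are converted to
expected chromosome counts (frequency × 2N, fractional) and pushed
through the same Haldane/χ²/Woolf/Šidák machinery as alleles, with n =
number of haplotypes tested. This treats the EM estimates as if they
were observed counts — phase uncertainty is *not* propagated — so any
row whose haplotype is estimated below 5 chromosomes in either group is
flagged `em_unstable`: near-zero cells both inflate the OR and
destabilize the maximum-likelihood frequencies themselves, and such rows
should be read as qualitative.

## Synthetic cohorts

The generator emulates the structure of a small-case/large-control HLA
study (defaults: 91 cases vs 350 fully typed controls, i.e. 182 vs 700
chromosomes) under three generative modes with unambiguous ground truth:
(1) independent per-locus allele-frequency vectors with each individual's
two alleles drawn i.i.d. (random mating, so HWE holds by construction);
(2) a two-subpopulation mixture in which each individual draws both
alleles from one of two divergent frequency vectors (Wahlund structure,
so HWE fails by construction); (3) explicit multi-locus haplotype
frequencies with two i.i.d. haplotype draws per individual, fixing the LD
structure exactly. Haplotype mode and allele mode are mutually exclusive
per group. Missingness is i.i.d. Bernoulli per (individual, locus) and
always whole-genotype, mirroring real locus-wise dropout. Everything is
deterministic given the seed.

`simulate_from_fixture` draws cohorts whose expected allele frequencies
equal the reference tables'; because the printed frequency lists do not
always sum to 1 (rare unlisted alleles), the residual mass is carried by
a clearly synthetic filler allele (`LOCUS*00:00:00`).

What the generator does *not* emulate: linkage between loci in allele
mode (each locus independent), recombination, family structure,
genotyping error, and covariate structure (age/sex). Consequently,
passing calibration tests demonstrates the correctness of the statistics
under their stated sampling models, not robustness to the messiness of
real registry data.

## Known limitations

- The crude p column is χ²-derived; covariate-adjusted (logistic
  regression) estimates are out of scope, and the reported ORs are
  labelled unadjusted (Woolf). For the sparse reference tables the
  adjusted and unadjusted estimates coincide numerically anyway.
- Haplotype tests use EM point estimates without phase-uncertainty
  propagation (see `em_unstable` above); no permutation p-values are
  provided for haplotypes.
- The HWE test is the omnibus conditional-probability version; one-sided
  heterozygote-deficit variants and Markov-chain samplers for loci with
  hundreds of alleles are not implemented (the permutation sampler is
  exact-in-the-limit and fast to ~50 alleles).
- Reference-table reconstruction depends on frequencies printed to five
  decimals; two published rows are internally inconsistent with their own
  frequencies and are deliberately not reproduced (the regression suite
  pins only verifiable rows).
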