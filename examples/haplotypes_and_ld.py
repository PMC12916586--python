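"""EM haplotype frequencies, pairwise LD, and haplotype association.

Simulates cases and controls from known Class II four-locus haplotype
frequencies (cases carry one enriched haplotype), re-estimates the
frequencies from the unphased genotypes with the gene-counting EM,
summarizes pairwise LD as mean |D'| and r^2, and tests each haplotype
for association.
"""

import numpy as np

from hlacc import em_haplotypes, haplotype_assoc, ld_matrix
from hlacc.simulate import GroupSpec, SynthConfig, simulate

LOCI = ("DRB1", "DQA1", "DQB1", "DPB1")
CONTROL = {
    ("DRB1*07:01:01", "DQA1*02:01:01", "DQB1*02:02:01", "DPB1*04:01:01"): 0.35,
    ("DRB1*15:01:01", "DQA1*01:02:01", "DQB1*06:02:01", "DPB1*04:01:01"): 0.30,
    ("DRB1*04:01:01", "DQA1*03:01:01", "DQB1*03:02:01", "DPB1*02:01:01"): 0.25,
    ("DRB1*01:01:01", "DQA1*01:01:01", "DQB1*05:01:01", "DPB1*04:02:01"): 0.10,
}
CASE = {  # first haplotype strongly enriched in cases
    list(CONTROL)[0]: 0.60,
    list(CONTROL)[1]: 0.20,
    list(CONTROL)[2]: 0.15,
    list(CONTROL)[3]: 0.05,
}

cfg = SynthConfig(
    91, 350, LOCI, GroupSpec(haplotype_freqs=CASE), GroupSpec(haplotype_freqs=CONTROL),
    seed=42,
)
cases, controls = simulate(cfg)

case_haps = em_haplotypes(cases, LOCI)
ctrl_haps = em_haplotypes(controls, LOCI)
print(f"EM: cases converged in {case_haps.n_iter} iterations, "
      f"controls in {ctrl_haps.n_iter}")
print("\nestimated case haplotype frequencies (truth in parentheses):")
for hap, truth in CASE.items():
    print(f"  {'~'.join(h.split('*')[1] for h in hap):40s} "
          f"{case_haps.freqs.get(hap, 0.0):.3f}  ({truth:.2f})")

ld = ld_matrix(controls, LOCI)
print("\ncontrol mean |D'| matrix (chromosomal locus order):")
with np.printoptions(precision=2, suppress=True):
    print("  " + " ".join(ld.loci))
    print(ld.dprime)

rows = haplotype_assoc(case_haps, ctrl_haps)
top = rows[0]
print(f"\nstrongest haplotype association: {top.allele}")
print(f"  freq {top.freq_case:.3f} vs {top.freq_control:.3f}, "
      f"chi2 = {top.chi2:.1f}, OR = {top.or_point:.2f}, "
      f"corrected p = {top.p_corrected:.2g}")
print(
    "\nFour-locus haplotypes built from one shared pool show near-complete "
    "pairwise LD; the enriched haplotype surfaces with a large chi-square "
    "even after correcting for the number of haplotypes tested."
)
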