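"""End-to-end orchestration: frequencies -> HWE -> association -> LD -> haplotypes.

``run_all`` takes genotype TSVs (or the built-in reference count tables)
and writes per-locus association tables, control-group HWE results,
per-group LD matrices, a Class II four-locus haplotype association table,
and a JSON manifest recording settings, seeds and output hashes so a rerun
with the same config is verifiably identical.  Count-only (fixture) input
cleanly gates the genotype-level stages rather than silently skipping
them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .association import AssocRow, run_locus
from .fixtures import table_fixtures
from .haplotypes import em_haplotypes, haplotype_assoc, ld_matrix
from .hwe import genotype_counts, hwe_exact_mc
from .io import CohortTable, count_alleles, read_cohort
from .nomenclature import CLASS_II, LOCI

log = logging.getLogger("hlacc")

ASSOC_COLUMNS = (
    "allele\tfreq_case\tfreq_control\tchi2\tp_chi2\tp_fisher\tor\tci_low\tci_high"
    "\tp_corrected\tasr\tzero_cell_adjusted"
)


@dataclass
class RunConfig:
    cases_path: str | None = None
    controls_path: str | None = None
    fixture_mode: bool = False
    loci: tuple[str, ...] | None = None
    yates: bool = False
    ld_weighting: str = "frequency"
    hwe_replicates: int = 10_000
    seed: int = 0
    out_dir: str = "hlacc_out"
    alpha: float = 0.05
    heatmap: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not self.fixture_mode and (not self.cases_path or not self.controls_path):
            raise ValueError("need cases and controls paths unless fixture_mode")


def format_p(p: float) -> str:
    """Three-decimal p-value notation with the '<.001' floor."""
    if p < 0.001:
        return "<.001"
    s = f"{p:.3f}"
    return s[1:] if s.startswith("0.") else s


def format_or_ci(or_point: float, ci_low: float, ci_high: float) -> str:
    return f"{or_point:.3f} ({ci_low:.3f}, {ci_high:.3f})"


def render_tables(rows: list[AssocRow], title: str = "") -> str:
    """Human-readable report table in the style of a journal allele table."""
    lines = []
    if title:
        lines.append(title)
    lines.append("allele\tfreq_case\tfreq_control\tchi2\tp\tOR (95% CI)\tcorrected p")
    for r in rows:
        lines.append(
            f"{r.allele}\t{r.freq_case:.5f}\t{r.freq_control:.5f}\t{r.chi2:.3f}\t"
            f"{format_p(r.p_chi2)}\t{format_or_ci(r.or_point, r.ci_low, r.ci_high)}\t"
            f"{format_p(r.p_corrected)}"
        )
    return "\n".join(lines)


def _assoc_tsv(rows: list[AssocRow]) -> str:
    lines = [ASSOC_COLUMNS]
    for r in rows:
        fisher = "" if r.p_fisher is None else f"{r.p_fisher:.6g}"
        asr = "" if r.asr is None else f"{r.asr:.4f}"
        lines.append(
            f"{r.allele}\t{r.freq_case:.5f}\t{r.freq_control:.5f}\t{r.chi2:.3f}\t"
            f"{r.p_chi2:.6g}\t{fisher}\t{r.or_point:.3f}\t{r.ci_low:.3f}\t"
            f"{r.ci_high:.3f}\t{r.p_corrected:.6g}\t{asr}\t"
            f"{int(r.zero_cell_adjusted)}"
        )
    return "\n".join(lines) + "\n"


def _rows_json(rows: list[AssocRow]) -> list[dict]:
    return [
        {**asdict(r), "allele": str(r.allele)}  # full precision, serializable
        for r in rows
    ]


def _ld_tsv(loci, matrix) -> str:
    lines = ["\t".join(("locus",) + tuple(loci))]
    for locus, row in zip(loci, matrix):
        lines.append(locus + "\t" + "\t".join(f"{x:.6f}" for x in row))
    return "\n".join(lines) + "\n"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run every stage the input supports; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "hlacc_version": __version__,
        "settings": {**asdict(config)},
        "stages": {},
        "outputs": {},
    }
    written: list[Path] = []

    def stage(name: str, **info):
        log.info("stage=%s %s", name, info)
        manifest["stages"][name] = info

    t0 = time.time()
    if config.fixture_mode:
        tables = table_fixtures()
        if config.loci:
            tables = {l: tables[l] for l in config.loci}
        cases = controls = None
        stage("load", mode="fixture", loci=list(tables))
    else:
        cases = read_cohort(config.cases_path, group="case")
        controls = read_cohort(config.controls_path, group="control")
        loci = config.loci or tuple(l for l in LOCI if l in cases.loci and l in controls.loci)
        tables = {l: count_alleles(cases, controls, l) for l in loci}
        stage(
            "load",
            mode="genotypes",
            n_cases=len(cases),
            n_controls=len(controls),
            loci=list(loci),
        )

    for locus, counts in tables.items():
        rows = run_locus(counts, yates=config.yates)
        path = out / f"assoc_{locus}.tsv"
        path.write_text(_assoc_tsv(rows))
        written.append(path)
        jpath = out / f"assoc_{locus}.json"
        jpath.write_text(json.dumps(_rows_json(rows), indent=1))
        written.append(jpath)
    stage("association", loci=list(tables), yates=config.yates)

    if cases is None:
        note = out / "genotype_stages.txt"
        note.write_text(
            "HWE, LD and haplotype stages require genotype-level input; "
            "count-table (fixture) input supports association statistics only.\n"
        )
        written.append(note)
        stage("genotype_stages", skipped="requires genotype-level input")
    else:
        seedseq = np.random.SeedSequence(config.seed)
        hwe_seeds = seedseq.generate_state(len(controls.loci))
        lines = ["locus\tn_individuals\tn_alleles\tp_value\tn_replicates\tseed"]
        for locus, s in zip(controls.loci, hwe_seeds):
            g = genotype_counts(controls, locus)
            res = hwe_exact_mc(g, n_replicates=config.hwe_replicates, seed=int(s))
            lines.append(
                f"{locus}\t{res.n_individuals}\t{res.n_alleles}\t"
                f"{res.p_value:.6g}\t{res.n_replicates}\t{res.seed}"
            )
        path = out / "hwe_controls.tsv"
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
        stage("hwe", replicates=config.hwe_replicates, alpha=config.alpha)

        for label, cohort in (("cases", cases), ("controls", controls)):
            if len(cohort.loci) < 2:
                continue
            ld = ld_matrix(cohort, weighting=config.ld_weighting)
            for kind, matrix in (("dprime", ld.dprime), ("rsq", ld.rsq)):
                path = out / f"ld_{kind}_{label}.tsv"
                path.write_text(_ld_tsv(ld.loci, matrix))
                written.append(path)
            if config.heatmap:
                png = out / f"ld_dprime_{label}.png"
                save_heatmap(ld, png)
                written.append(png)
        stage("ld", weighting=config.ld_weighting)

        class2 = tuple(l for l in CLASS_II if l in cases.loci and l in controls.loci)
        if len(class2) >= 2:
            case_haps = em_haplotypes(cases, class2)
            ctrl_haps = em_haplotypes(controls, class2)
            rows = haplotype_assoc(case_haps, ctrl_haps)
            path = out / "haplotype_assoc.tsv"
            header = (
                "haplotype\tfreq_case\tfreq_control\tchi2\tor\tci_low\tci_high"
                "\tp_corrected\tem_unstable"
            )
            lines = [header]
            for r in rows:
                lines.append(
                    f"{r.allele}\t{r.freq_case:.5f}\t{r.freq_control:.5f}\t"
                    f"{r.chi2:.3f}\t{r.or_point:.3f}\t{r.ci_low:.3f}\t"
                    f"{r.ci_high:.3f}\t{r.p_corrected:.6g}\t{int(r.em_unstable)}"
                )
            path.write_text("\n".join(lines) + "\n")
            written.append(path)
            stage(
                "haplotypes",
                loci=list(class2),
                n_haplotypes=len(rows),
                case_converged=case_haps.converged,
                control_converged=ctrl_haps.converged,
            )

    manifest["outputs"] = {p.name: _sha256(p) for p in written}
    manifest["wall_time_s"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def save_heatmap(ld, path, cmap: str = "Blues") -> None:
    """Export a mean-|D'| heatmap (white = weak, dark = strong LD)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(ld.dprime, cmap=cmap, vmin=0, vmax=1)
    ax.set_xticks(range(len(ld.loci)), ld.loci, rotation=45)
    ax.set_yticks(range(len(ld.loci)), ld.loci)
    fig.colorbar(im, ax=ax, label="mean |D'|")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
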