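"""Genotype and allele-count containers plus TSV readers/writers.

The genotype table format is one row per individual with two columns per
locus (``A_1``, ``A_2``, ...).  An individual is either fully typed at a
locus (two allele calls; homozygotes repeat the allele) or missing the
locus entirely — a single non-empty cell is rejected as a half-missing
genotype.  Missingness is handled locus-wise: a record missing DRB1 still
contributes its chromosomes at every other locus, so per-locus chromosome
denominators (2N) are always derived from the data, never assumed from the
nominal sample size.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .nomenclature import LOCI, AlleleName, parse_allele


class CohortFormatError(ValueError):
    """Raised on malformed genotype tables."""


@dataclass(frozen=True)
class GenotypeRecord:
    """Unphased genotypes for one individual across up to seven loci."""

    sample_id: str
    group: str
    genotype: Mapping[str, tuple[AlleleName, AlleleName] | None]

    def __post_init__(self) -> None:
        for locus, pair in self.genotype.items():
            if pair is None:
                continue
            a, b = pair
            if a.locus != locus or b.locus != locus:
                raise CohortFormatError(
                    f"sample {self.sample_id}: allele from wrong locus in "
                    f"{locus} column ({a}, {b})"
                )


@dataclass
class CohortTable:
    """All genotype records for one group, with per-locus missingness."""

    records: list[GenotypeRecord]
    loci: tuple[str, ...]
    group: str = ""

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortFormatError(f"duplicate sample_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def n_typed(self, locus: str) -> int:
        return sum(1 for r in self.records if r.genotype.get(locus) is not None)

    def chromosomes(self, locus: str) -> int:
        """2 x number of records typed at *locus*."""
        return 2 * self.n_typed(locus)

    def alleles_at(self, locus: str) -> Iterable[AlleleName]:
        for r in self.records:
            pair = r.genotype.get(locus)
            if pair is not None:
                yield from pair


@dataclass
class AlleleCountTable:
    """Per-locus chromosome counts of each allele in cases and controls.

    This is the unit of association testing: ``rows`` maps each allele
    observed in either group to ``(case_count, control_count)`` and the
    ``*_total_2n`` fields hold the per-group chromosome denominators.
    """

    locus: str
    rows: dict[AlleleName, tuple[int, int]]
    case_total_2n: int
    control_total_2n: int

    def __post_init__(self) -> None:
        if self.case_total_2n <= 0 or self.control_total_2n <= 0:
            raise ValueError("chromosome totals must be positive")
        case_sum = sum(a for a, _ in self.rows.values())
        ctrl_sum = sum(b for _, b in self.rows.values())
        if case_sum > self.case_total_2n or ctrl_sum > self.control_total_2n:
            raise ValueError(
                f"{self.locus}: allele counts exceed chromosome totals "
                f"({case_sum}/{self.case_total_2n}, {ctrl_sum}/{self.control_total_2n})"
            )
        for allele, (a, b) in self.rows.items():
            if a < 0 or b < 0:
                raise ValueError(f"negative count for {allele}")

    @property
    def n_alleles(self) -> int:
        return len(self.rows)

    def freq_case(self, allele: AlleleName) -> float:
        return self.rows[allele][0] / self.case_total_2n

    def freq_control(self, allele: AlleleName) -> float:
        return self.rows[allele][1] / self.control_total_2n


def _locus_columns(loci: Iterable[str]) -> list[str]:
    cols = []
    for locus in loci:
        cols += [f"{locus}_1", f"{locus}_2"]
    return cols


def read_cohort(path: str | Path | _io.StringIO, group: str | None = None) -> CohortTable:
    """Read a genotype TSV into a :class:`CohortTable`.

    The file must have a ``sample_id`` column, optionally a ``group``
    column, and two columns per locus.  If *group* is given and the file
    has a group column, rows are filtered to that group.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise CohortFormatError("missing 'sample_id' column")
    has_group = "group" in df.columns
    if group is not None and has_group:
        df = df[df["group"] == group]
    loci = tuple(l for l in LOCI if f"{l}_1" in df.columns or f"{l}_2" in df.columns)
    for locus in loci:
        if f"{locus}_1" not in df.columns or f"{locus}_2" not in df.columns:
            raise CohortFormatError(f"locus {locus} needs both _1 and _2 columns")
    if not loci:
        raise CohortFormatError("no locus columns found")

    records = []
    for _, row in df.iterrows():
        genotype: dict[str, tuple[AlleleName, AlleleName] | None] = {}
        for locus in loci:
            c1, c2 = row[f"{locus}_1"].strip(), row[f"{locus}_2"].strip()
            if not c1 and not c2:
                genotype[locus] = None
            elif c1 and c2:
                genotype[locus] = (parse_allele(c1), parse_allele(c2))
            else:
                raise CohortFormatError(
                    f"sample {row['sample_id']}: half-missing genotype at {locus}"
                )
        grp = row["group"] if has_group else (group or "")
        records.append(GenotypeRecord(row["sample_id"], grp, genotype))
    return CohortTable(records, loci, group or (records[0].group if records else ""))


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write the standard genotype TSV (inverse of :func:`read_cohort`)."""
    cols = ["sample_id", "group"] + _locus_columns(cohort.loci)
    out = []
    for r in cohort.records:
        row = {"sample_id": r.sample_id, "group": r.group}
        for locus in cohort.loci:
            pair = r.genotype.get(locus)
            row[f"{locus}_1"] = str(pair[0]) if pair else ""
            row[f"{locus}_2"] = str(pair[1]) if pair else ""
        out.append(row)
    pd.DataFrame(out, columns=cols).to_csv(path, sep="\t", index=False)


def count_alleles(cases: CohortTable, controls: CohortTable, locus: str) -> AlleleCountTable:
    """Gene counting: chromosomes carrying each allele, per group.

    Every allele observed in either group appears in the output; an allele
    absent from one group keeps its zero cell (zero-frequency cells are the
    substance of sparse-table statistics, not noise to drop).
    """
    case_2n = cases.chromosomes(locus)
    ctrl_2n = controls.chromosomes(locus)
    if case_2n == 0 and ctrl_2n == 0:
        raise ValueError(f"locus {locus} untyped in both cohorts")
    case_counts: dict[AlleleName, int] = {}
    ctrl_counts: dict[AlleleName, int] = {}
    for a in cases.alleles_at(locus):
        case_counts[a] = case_counts.get(a, 0) + 1
    for a in controls.alleles_at(locus):
        ctrl_counts[a] = ctrl_counts.get(a, 0) + 1
    alleles = sorted(set(case_counts) | set(ctrl_counts))
    rows = {a: (case_counts.get(a, 0), ctrl_counts.get(a, 0)) for a in alleles}
    return AlleleCountTable(locus, rows, max(case_2n, 1), max(ctrl_2n, 1))


def write_counts(tables: Mapping[str, AlleleCountTable], path: str | Path) -> None:
    """Write count tables as TSV with a totals header comment."""
    lines = []
    totals = ";".join(
        f"{t.locus}:{t.case_total_2n}/{t.control_total_2n}" for t in tables.values()
    )
    lines.append(f"# totals_2n {totals}")
    lines.append("locus\tallele\tcase_count\tcontrol_count")
    for t in tables.values():
        for allele, (a, b) in t.rows.items():
            lines.append(f"{t.locus}\t{allele}\t{a}\t{b}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_counts(path: str | Path) -> dict[str, AlleleCountTable]:
    """Inverse of :func:`write_counts`."""
    text = Path(path).read_text().splitlines()
    if not text or not text[0].startswith("# totals_2n "):
        raise CohortFormatError("count table missing totals header comment")
    totals: dict[str, tuple[int, int]] = {}
    for part in text[0].removeprefix("# totals_2n ").split(";"):
        locus, _, frac = part.partition(":")
        a, _, b = frac.partition("/")
        totals[locus] = (int(a), int(b))
    rows_by_locus: dict[str, dict[AlleleName, tuple[int, int]]] = {}
    for line in text[2:]:
        if not line.strip():
            continue
        locus, allele, a, b = line.split("\t")
        rows_by_locus.setdefault(locus, {})[parse_allele(allele)] = (int(a), int(b))
    return {
        locus: AlleleCountTable(locus, rows, *totals[locus])
        for locus, rows in rows_by_locus.items()
    }
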