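"""Reference allele-frequency tables and their integer-count reconstruction.

A published aplastic-anemia case-control study of ethnic Kazakhs reports
per-allele frequencies at seven HLA loci to five decimals.  Multiplying
each frequency by the locus-specific chromosome totals recovers the
underlying integer chromosome counts exactly (every product lands within
0.02 of an integer), which makes the printed tables usable as regression
fixtures for the whole association stack without the deposited raw data.

Chromosome totals are inferred from the arithmetic of the printed
frequencies themselves: 182 case chromosomes at A/C/B/DQB1/DPB1 and 180 at
DRB1/DQA1 (one case apparently untyped at those two loci), and 700 control
chromosomes at every locus.  The totals are validated, not assumed: the
reconstruction raises if any frequency fails to land on an integer.
"""

from __future__ import annotations

from .io import AlleleCountTable
from .nomenclature import parse_allele

#: Case chromosome totals differ by locus (locus-wise missingness).
CASE_2N = {"A": 182, "C": 182, "B": 182, "DRB1": 180, "DQA1": 180, "DQB1": 182, "DPB1": 182}
CONTROL_2N = 700

#: Reconstruction tolerance: frequency x total must be this close to an integer.
INTEGER_TOL = 0.02


class FixtureIntegrityError(ValueError):
    """A printed frequency fails to reconstruct to an integer count."""


# (allele, case frequency, control frequency), per locus, as printed.
_FREQS: dict[str, list[tuple[str, float, float]]] = {
    "A": [
        ("A*33:01:01", 0.01648, 0.00714),
        ("A*26:01:01", 0.06044, 0.05000),
        ("A*29:01:01", 0.01099, 0.01571),
        ("A*32:01:01", 0.02198, 0.02714),
        ("A*30:01:01", 0.02198, 0.01857),
        ("A*01:01:01", 0.07692, 0.08571),
        ("A*68:01:02", 0.01648, 0.03429),
        ("A*31:01:02", 0.04396, 0.04714),
        ("A*24:02:01", 0.22527, 0.18857),
        ("A*02:01:01", 0.20330, 0.17714),
        ("A*02:05:01", 0.01648, 0.01000),
        ("A*02:06:01", 0.06593, 0.03429),
        ("A*02:07:01", 0.01099, 0.02857),
        ("A*33:03:01", 0.03846, 0.05286),
        ("A*03:01:01", 0.05495, 0.06286),
        ("A*03:02:01", 0.01648, 0.00429),
        ("A*11:01:01", 0.04945, 0.08857),
        ("A*23:01:01", 0.01648, 0.01857),
    ],
    "C": [
        ("C*07:06:01", 0.01099, 0.00000),
        ("C*08:01:01", 0.04396, 0.01714),
        ("C*04:01:01", 0.05495, 0.10714),
        ("C*07:02:01", 0.15385, 0.10286),
        ("C*03:04:01", 0.12637, 0.08286),
        ("C*07:04:01", 0.01099, 0.03429),
        ("C*15:02:01", 0.02747, 0.05714),
        ("C*12:03:01", 0.03846, 0.07143),
        ("C*16:04:01", 0.01099, 0.00286),
        ("C*05:01:01", 0.03846, 0.02286),
        ("C*02:02:02", 0.01648, 0.03143),
        ("C*03:03:01", 0.05495, 0.03714),
        ("C*12:02:02", 0.01099, 0.00429),
        ("C*08:02:01", 0.02747, 0.01571),
        ("C*06:02:01", 0.10440, 0.12429),
        ("C*08:03:01", 0.00549, 0.01143),
        ("C*14:02:01", 0.02198, 0.02571),
        ("C*12:02:01", 0.02747, 0.03143),
        ("C*01:02:01", 0.07143, 0.07286),
        ("C*07:01:01", 0.05495, 0.05429),
        ("C*03:02:02", 0.05495, 0.05429),
    ],
    "B": [
        ("B*40:02:01", 0.11538, 0.05286),
        ("B*44:03:02", 0.01099, 0.00000),
        ("B*67:01:01", 0.01099, 0.00000),
        ("B*73:01:01", 0.01099, 0.00143),
        ("B*07:02:01", 0.09341, 0.05857),
        ("B*54:01:01", 0.03297, 0.01429),
        ("B*49:01:01", 0.03297, 0.01429),
        ("B*44:03:01", 0.00549, 0.02143),
        ("B*44:02:01", 0.04396, 0.02429),
        ("B*35:01:01", 0.02747, 0.05143),
        ("B*40:01:01", 0.00000, 0.01429),
        ("B*38:01:01", 0.01099, 0.02714),
        ("B*27:05:02", 0.01099, 0.02714),
        ("B*46:01:01", 0.01099, 0.02571),
        ("B*18:01:01", 0.01648, 0.03143),
        ("B*14:02:01", 0.02747, 0.01571),
        ("B*15:18:01", 0.01099, 0.02143),
        ("B*35:03:01", 0.03297, 0.04571),
        ("B*37:01:01", 0.01648, 0.01000),
        ("B*13:02:01", 0.05495, 0.07000),
        ("B*48:01:01", 0.03846, 0.02857),
        ("B*15:01:01", 0.02198, 0.03143),
        ("B*52:01:01", 0.02747, 0.03571),
        ("B*35:02:01", 0.01099, 0.00714),
        ("B*57:01:01", 0.01099, 0.01571),
        ("B*39:01:01L", 0.01099, 0.01571),
        ("B*50:01:01", 0.02198, 0.02714),
        ("B*51:01:01", 0.07143, 0.08000),
        ("B*40:06:01", 0.01099, 0.01429),
        ("B*08:01:01", 0.03297, 0.03714),
        ("B*58:01:01", 0.05495, 0.06000),
    ],
    "DRB1": [
        ("DRB1*05:05:01", 0.15556, 0.00000),
        ("DRB1*01:02:01", 0.18333, 0.00857),
        ("DRB1*03:03:01", 0.11111, 0.00000),
        ("DRB1*05:01:01", 0.11111, 0.00000),
        ("DRB1*02:01:01", 0.10556, 0.00000),
        ("DRB1*01:03:01", 0.08333, 0.00000),
        ("DRB1*03:02:01", 0.05556, 0.00000),
        ("DRB1*01:04:01", 0.04444, 0.00000),
        ("DRB1*07:01:01", 0.00000, 0.12714),
        ("DRB1*15:01:01", 0.00000, 0.09571),
        ("DRB1*06:01:01", 0.01667, 0.00000),
        ("DRB1*05:03:01", 0.01667, 0.00000),
        ("DRB1*04:01:01", 0.01667, 0.08714),
        ("DRB1*13:01:01", 0.00000, 0.05571),
        ("DRB1*14:01:01", 0.00000, 0.04429),
        ("DRB1*01:05:01", 0.01111, 0.00000),
        ("DRB1*11:01:01", 0.00000, 0.04286),
        ("DRB1*03:01:01", 0.03889, 0.10143),
        ("DRB1*13:02:01", 0.00000, 0.03714),
        ("DRB1*12:01:01", 0.00000, 0.03429),
        ("DRB1*09:01:02", 0.00000, 0.03286),
        ("DRB1*15:02:01", 0.00000, 0.03000),
        ("DRB1*01:01:01", 0.03333, 0.07429),
    ],
    "DQA1": [
        ("DQA1*05:05:01", 0.15556, 0.00000),
        ("DQA1*03:03:01", 0.11111, 0.00000),
        ("DQA1*03:02:01", 0.05556, 0.00000),
        ("DQA1*01:04:01", 0.04444, 0.00000),
        ("DQA1*03:01:01", 0.03889, 0.20857),
        ("DQA1*01:01:01", 0.03333, 0.15714),
        ("DQA1*05:01:01", 0.11111, 0.22143),
        ("DQA1*01:05:01", 0.01111, 0.00000),
        ("DQA1*01:01:02", 0.00556, 0.00000),
        ("DQA1*01:02:01", 0.18333, 0.13714),
        ("DQA1*01:03:01", 0.08333, 0.11143),
        ("DQA1*02:01:01", 0.10556, 0.12714),
        ("DQA1*04:01:01", 0.01667, 0.01000),
        ("DQA1*06:01:01", 0.01667, 0.02571),
    ],
    "DQB1": [
        ("DQB1*02:02:01", 0.08791, 0.00000),
        ("DQB1*02:01:01", 0.11538, 0.21143),
        ("DQB1*06:02:01", 0.14835, 0.08143),
        ("DQB1*05:01:01", 0.04396, 0.09571),
        ("DQB1*04:01:01", 0.03297, 0.01429),
        ("DQB1*05:03:01", 0.01648, 0.04000),
        ("DQB1*06:01:01", 0.03297, 0.06143),
        ("DQB1*03:02:01", 0.05495, 0.08000),
        ("DQB1*03:03:02", 0.06593, 0.04571),
        ("DQB1*03:01:01", 0.25275, 0.21714),
        ("DQB1*05:02:01", 0.04396, 0.03143),
        ("DQB1*06:04:01", 0.01648, 0.02571),
        ("DQB1*06:03:01", 0.04945, 0.05571),
        ("DQB1*04:02:01", 0.01648, 0.01429),
        ("DQB1*06:09:01", 0.01099, 0.01143),
    ],
    "DPB1": [
        ("DPB1*02:01:02", 0.07143, 0.00000),
        ("DPB1*104:01:01", 0.03297, 0.00000),
        ("DPB1*02:01:01", 0.07692, 0.17714),
        ("DPB1*05:01:01", 0.12637, 0.07429),
        ("DPB1*04:01:01", 0.40110, 0.32714),
        ("DPB1*03:01:01", 0.06044, 0.09143),
        ("DPB1*04:02:01", 0.09341, 0.12857),
        ("DPB1*17:01:01", 0.02198, 0.04000),
        ("DPB1*02:02:01", 0.00549, 0.01571),
        ("DPB1*14:01:01", 0.01099, 0.01857),
        ("DPB1*36:01:01", 0.00000, 0.00571),
        ("DPB1*13:01:01", 0.02198, 0.03000),
        ("DPB1*09:01:01", 0.02198, 0.02286),
        ("DPB1*15:01:01", 0.01099, 0.01143),
    ],
}


def reference_frequencies() -> dict[str, list[tuple[str, float, float]]]:
    """The published per-locus (allele, case freq, control freq) triples."""
    return {locus: list(rows) for locus, rows in _FREQS.items()}


def _reconstruct(freq: float, total: int, allele: str) -> int:
    x = freq * total
    k = round(x)
    if abs(x - k) > INTEGER_TOL:
        raise FixtureIntegrityError(
            f"{allele}: {freq} x {total} = {x:.4f} is not within "
            f"{INTEGER_TOL} of an integer"
        )
    return int(k)


def table_fixtures() -> dict[str, AlleleCountTable]:
    """Integer count tables reconstructed from the printed frequencies.

    Raises :class:`FixtureIntegrityError` if any frequency does not
    reconstruct to an integer count — this validates both the transcribed
    frequencies and the inferred chromosome totals.
    """
    out: dict[str, AlleleCountTable] = {}
    for locus, rows in _FREQS.items():
        case_2n = CASE_2N[locus]
        table = {}
        for name, f_case, f_ctrl in rows:
            allele = parse_allele(name)
            table[allele] = (
                _reconstruct(f_case, case_2n, name),
                _reconstruct(f_ctrl, CONTROL_2N, name),
            )
        out[locus] = AlleleCountTable(locus, table, case_2n, CONTROL_2N)
    return out
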