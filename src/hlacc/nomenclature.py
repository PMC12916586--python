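"""Parsing and formatting of HLA allele names.

HLA alleles are written in colon-delimited nomenclature: a locus token, an
asterisk, one to four numeric fields, and an optional single-letter
expression suffix (e.g. ``B*39:01:01L`` for a low-expression variant).
Three fields ("six-digit" resolution) distinguish synonymous coding
variants such as ``DPB1*02:01:01`` vs ``DPB1*02:01:02`` — a distinction
this toolkit never collapses by default, since closely related alleles can
carry opposite disease associations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The seven classical loci handled here, in chromosomal order on 6p21.
LOCI: tuple[str, ...] = ("A", "C", "B", "DRB1", "DQA1", "DQB1", "DPB1")
CLASS_I: tuple[str, ...] = ("A", "C", "B")
CLASS_II: tuple[str, ...] = ("DRB1", "DQA1", "DQB1", "DPB1")


class AlleleParseError(ValueError):
    """Raised when a string is not a well-formed HLA allele name."""


@dataclass(frozen=True, order=True)
class AlleleName:
    """A structured HLA allele identifier.

    Equality is exact field-by-field string equality including the
    expression suffix: ``B*39:01:01L != B*39:01:01``.  Fields keep their
    zero padding so that formatting round-trips the original string.
    """

    locus: str
    fields: tuple[str, ...]
    expression_suffix: str = ""

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise AlleleParseError(f"unknown HLA locus {self.locus!r}")
        if not 1 <= len(self.fields) <= 4:
            raise AlleleParseError(
                f"allele must have 1-4 fields, got {len(self.fields)}"
            )
        for tok in self.fields:
            if not tok or not tok.isdigit():
                raise AlleleParseError(f"non-numeric allele field {tok!r}")
        if self.expression_suffix and not (
            len(self.expression_suffix) == 1 and self.expression_suffix.isalpha()
        ):
            raise AlleleParseError(
                f"expression suffix must be one letter, got {self.expression_suffix!r}"
            )

    @property
    def resolution(self) -> int:
        """Number of numeric fields (3 = six-digit resolution)."""
        return len(self.fields)

    def truncate(self, n_fields: int) -> "AlleleName":
        """Roll up to a lower resolution (explicit opt-in; never implicit)."""
        if not 1 <= n_fields <= len(self.fields):
            raise ValueError(f"cannot truncate to {n_fields} fields")
        return AlleleName(self.locus, self.fields[:n_fields], "")

    def __str__(self) -> str:
        return f"{self.locus}*{':'.join(self.fields)}{self.expression_suffix}"


def parse_allele(s: str) -> AlleleName:
    """Parse ``LOCUS*NN:NN:NN[X]`` into an :class:`AlleleName`.

    Raises :class:`AlleleParseError` naming the offending token on any
    malformed input.  ``format(parse_allele(s)) == s`` for every accepted
    string.
    """
    if "*" not in s:
        raise AlleleParseError(f"missing '*' separator in {s!r}")
    locus, _, rest = s.partition("*")
    if locus not in LOCI:
        raise AlleleParseError(f"unknown HLA locus {locus!r} in {s!r}")
    suffix = ""
    if rest and rest[-1].isalpha():
        suffix, rest = rest[-1], rest[:-1]
    if not rest:
        raise AlleleParseError(f"no numeric fields in {s!r}")
    toks = rest.split(":")
    if len(toks) > 4:
        raise AlleleParseError(f"more than 4 fields in {s!r}")
    for tok in toks:
        if not tok or not tok.isdigit():
            raise AlleleParseError(f"non-numeric field {tok!r} in {s!r}")
    return AlleleName(locus, tuple(toks), suffix)


def format_allele(a: AlleleName) -> str:
    """Inverse of :func:`parse_allele`."""
    return str(a)
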