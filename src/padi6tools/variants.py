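"""Protein variants, genotypes, subjects and cohort tables.

Variants are expressed in protein HGVS-like notation against the hPADI6
protein sequence (author numbering 1-694, matching the deposited model).
Only protein-level consequences are modelled: missense, synonymous, and
"null" (truncating: stop-gain, frameshift, start-loss). Splice and
DNA-level notation are out of scope and rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

AA1 = "ACDEFGHIKLMNPQRSTVWY"

AA3_TO_1 = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}

#: tokens in the alt position that denote a truncating (protein-null) allele
_NULL_TOKENS = {"*", "X", "TER", "FS"}

_GROUPS = ("infertility", "HM", "MLID", "gnomad_het", "gnomad_hom", "primad_hom")


class Consequence(str, Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    NULL = "null"


class VariantParseError(ValueError):
    """Raised when a variant or genotype token cannot be interpreted."""


@dataclass(frozen=True)
class ProteinVariant:
    """A single-residue protein change.

    ``alt_aa`` is ``None`` for truncating alleles (consequence ``null``).
    """

    position: int
    ref_aa: str
    alt_aa: str | None
    consequence: Consequence

    def __post_init__(self) -> None:
        if self.position < 1:
            raise VariantParseError(f"position must be >= 1, got {self.position}")
        if self.ref_aa not in AA1:
            raise VariantParseError(f"unknown reference residue {self.ref_aa!r}")
        if self.consequence is Consequence.NULL:
            if self.alt_aa is not None:
                raise VariantParseError("null variants carry no alt residue")
        else:
            if self.alt_aa not in AA1:
                raise VariantParseError(f"unknown alternate residue {self.alt_aa!r}")
            if self.consequence is Consequence.MISSENSE and self.alt_aa == self.ref_aa:
                raise VariantParseError("missense requires alt != ref")
            if self.consequence is Consequence.SYNONYMOUS and self.alt_aa != self.ref_aa:
                raise VariantParseError("synonymous requires alt == ref")


class AlleleKind(str, Enum):
    WILD_TYPE = "wild_type"
    VARIANT = "variant"


@dataclass(frozen=True)
class Allele:
    kind: AlleleKind
    variant: ProteinVariant | None = None

    def __post_init__(self) -> None:
        if self.kind is AlleleKind.WILD_TYPE and self.variant is not None:
            raise VariantParseError("wild-type alleles carry no variant")
        if self.kind is AlleleKind.VARIANT and self.variant is None:
            raise VariantParseError("variant alleles require a ProteinVariant")

    @classmethod
    def wild_type(cls) -> "Allele":
        return cls(AlleleKind.WILD_TYPE)

    @classmethod
    def of(cls, variant: ProteinVariant) -> "Allele":
        return cls(AlleleKind.VARIANT, variant)


@dataclass(frozen=True)
class Genotype:
    """Two alleles; order carries no meaning (phasing unknown in this study)."""

    allele1: Allele
    allele2: Allele
    phased: bool = False

    @property
    def alleles(self) -> tuple[Allele, Allele]:
        return (self.allele1, self.allele2)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genotype):
            return NotImplemented
        a, b = self.alleles, other.alleles
        return (a == b or a == b[::-1]) and self.phased == other.phased

    def __hash__(self) -> int:
        return hash((frozenset([self.allele1, self.allele2]), self.phased))


@dataclass(frozen=True)
class Subject:
    id: str
    genotype: Genotype
    group: str

    def __post_init__(self) -> None:
        if self.group not in _GROUPS:
            raise VariantParseError(
                f"unknown group {self.group!r}; expected one of {_GROUPS}"
            )
        n_var = sum(a.kind is AlleleKind.VARIANT for a in self.genotype.alleles)
        if self.group == "gnomad_het" and n_var != 1:
            raise VariantParseError(
                f"subject {self.id}: gnomad_het requires exactly one variant allele"
            )
        if self.group.endswith("_hom"):
            a1, a2 = self.genotype.alleles
            if not (a1.kind is AlleleKind.VARIANT and a1 == a2):
                raise VariantParseError(
                    f"subject {self.id}: {self.group} requires two identical variant alleles"
                )


_VARIANT_RE = re.compile(
    r"^(?:p\.)?"
    r"(?P<ref>[A-Za-z]{1,3})"
    r"(?P<pos>\d+)"
    r"(?P<alt>\*|[A-Za-z]{1,3})$"
)


def _residue_code(token: str, context: str) -> str:
    token = token.strip()
    if len(token) == 1:
        code = token.upper()
        if code not in AA1:
            raise VariantParseError(f"unknown residue code {token!r} in {context!r}")
        return code
    code = AA3_TO_1.get(token.upper())
    if code is None:
        raise VariantParseError(f"unknown residue code {token!r} in {context!r}")
    return code


def parse_variant(text: str) -> ProteinVariant:
    """Parse HGVS-protein-like notation such as ``p.N598S`` or ``p.Q78Ter``.

    Accepts one- and three-letter residue codes; truncation tokens
    (``*``, ``X``, ``Ter``, ``fs``) yield a null-consequence variant.
    """
    token = text.strip()
    if not token:
        raise VariantParseError("empty variant token")
    if token.lower().startswith("c."):
        raise VariantParseError(
            f"DNA-level notation not supported: {text!r} (protein-level only)"
        )
    m = _VARIANT_RE.match(token)
    if m is None:
        raise VariantParseError(f"malformed variant token {text!r}")
    position = int(m.group("pos"))
    if position == 0:
        raise VariantParseError(f"position 0 is invalid in {text!r}")
    ref = _residue_code(m.group("ref"), text)
    alt_token = m.group("alt")
    if alt_token.upper() in _NULL_TOKENS:
        return ProteinVariant(position, ref, None, Consequence.NULL)
    alt = _residue_code(alt_token, text)
    consequence = Consequence.SYNONYMOUS if alt == ref else Consequence.MISSENSE
    return ProteinVariant(position, ref, alt, consequence)


def format_variant(v: ProteinVariant) -> str:
    alt = "Ter" if v.consequence is Consequence.NULL else v.alt_aa
    return f"p.{v.ref_aa}{v.position}{alt}"


def parse_allele(text: str) -> Allele:
    token = text.strip()
    if token.upper() == "WT":
        return Allele.wild_type()
    return Allele.of(parse_variant(token))


def parse_genotype(text: str) -> Genotype:
    """Parse ``"alleleA/alleleB"``, a single allele, or ``"variant;hom"``.

    A lone variant token is read as a heterozygote with a wild-type second
    allele (the convention used for unphased single-variant carriers); a
    ``;hom`` suffix duplicates the allele.
    """
    token = text.strip()
    homozygous = False
    if token.lower().endswith(";hom"):
        homozygous = True
        token = token[: -len(";hom")].strip()
    parts = [p for p in (s.strip() for s in token.split("/")) if p]
    if not parts:
        raise VariantParseError(f"empty genotype {text!r}")
    if len(parts) > 2:
        raise VariantParseError(f"more than two alleles in {text!r}")
    if homozygous:
        if len(parts) != 1:
            raise VariantParseError(f";hom applies to a single allele, got {text!r}")
        a = parse_allele(parts[0])
        return Genotype(a, a)
    if len(parts) == 1:
        return Genotype(parse_allele(parts[0]), Allele.wild_type())
    return Genotype(parse_allele(parts[0]), parse_allele(parts[1]))


def format_genotype(g: Genotype) -> str:
    def fmt(a: Allele) -> str:
        return "WT" if a.kind is AlleleKind.WILD_TYPE else format_variant(a.variant)

    if g.allele1.kind is AlleleKind.VARIANT and g.allele1 == g.allele2:
        return f"{fmt(g.allele1)};hom"
    return f"{fmt(g.allele1)}/{fmt(g.allele2)}"


def read_cohort_table(path: str | Path) -> list[Subject]:
    """Read a tab-delimited cohort table with columns id, genotype, group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"id", "genotype", "group"} - set(df.columns)
    if missing:
        raise VariantParseError(f"cohort table missing columns {sorted(missing)}")
    subjects: list[Subject] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        sid = str(row["id"]).strip()
        if sid in seen:
            raise VariantParseError(f"duplicate subject id {sid!r} at row {rowno}")
        seen.add(sid)
        try:
            genotype = parse_genotype(str(row["genotype"]))
            subjects.append(Subject(sid, genotype, str(row["group"]).strip()))
        except VariantParseError as err:
            raise VariantParseError(f"row {rowno} (id={sid!r}): {err}") from err
    return subjects


def write_cohort_table(subjects: Iterable[Subject], path: str | Path) -> None:
    rows = [
        {"id": s.id, "genotype": format_genotype(s.genotype), "group": s.group}
        for s in subjects
    ]
    pd.DataFrame(rows, columns=["id", "genotype", "group"]).to_csv(
        path, sep="\t", index=False
    )
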