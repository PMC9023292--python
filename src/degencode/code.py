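"""RNA base / codon-doublet vocabulary and reference degeneracy tables.

The unit of degeneracy classification is the *doublet*: the first two
codon bases N1N2, which define a 4x4 box of the genetic-code table.  The
anticodon pairs antiparallel, so anticodon position 36 reads codon
position 1 and position 35 reads position 2.  Degeneracy families are
box-level: a box is either split into a purine-ending and a
pyrimidine-ending half (two-fold) or fully synonymous (four-fold).
Singularities of the standard code (AUG, UGA...) are deliberately not
modelled; the built-in reference is the yeast/human mitochondrial code,
which is singularity-free at box level.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "Base",
    "Doublet",
    "DegeneracyFamily",
    "CodeTable",
    "BASE_ORDER",
    "PURINES",
    "PYRIMIDINES",
    "complement",
    "is_purine",
    "anticodon_bases",
    "permute_first_position",
    "known_degeneracy",
    "all_doublets",
    "get_code_table",
    "MITOCHONDRIAL",
]

#: Row/column enumeration order of the classic genetic-code table.
BASE_ORDER = ("U", "C", "A", "G")


class Base(str, enum.Enum):
    """One of the four RNA bases."""

    A = "A"
    C = "C"
    G = "G"
    U = "U"

    @classmethod
    def parse(cls, symbol: str, *, normalize_dna: bool = False) -> "Base":
        """Parse a one-letter base symbol.

        ``T`` is rejected unless ``normalize_dna=True``, in which case it
        is read as ``U``.  Lowercase input is accepted.
        """
        s = str(symbol).strip().upper()
        if s == "T":
            if normalize_dna:
                return cls.U
            raise ValueError(
                "DNA base 'T' not accepted; pass normalize_dna=True to read T as U"
            )
        try:
            return cls(s)
        except ValueError:
            raise ValueError(f"invalid RNA base symbol: {symbol!r}") from None

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


PURINES = frozenset({Base.A, Base.G})
PYRIMIDINES = frozenset({Base.C, Base.U})

_COMPLEMENT = {Base.A: Base.U, Base.U: Base.A, Base.G: Base.C, Base.C: Base.G}


def complement(b: Base | str) -> Base:
    """Watson-Crick partner of a base (involutive: A<->U, G<->C)."""
    if not isinstance(b, Base):
        b = Base.parse(b)
    return _COMPLEMENT[b]


def is_purine(b: Base | str) -> bool:
    if not isinstance(b, Base):
        b = Base.parse(b)
    return b in PURINES


@dataclass(frozen=True, order=True)
class Doublet:
    """First two codon bases N1N2 -- one box of the code table."""

    n1: Base
    n2: Base

    @classmethod
    def parse(cls, text: str, *, normalize_dna: bool = False) -> "Doublet":
        t = str(text).strip()
        if len(t) != 2:
            raise ValueError(f"a doublet needs exactly two bases, got {text!r}")
        return cls(
            Base.parse(t[0], normalize_dna=normalize_dna),
            Base.parse(t[1], normalize_dna=normalize_dna),
        )

    def __str__(self) -> str:
        return f"{self.n1.value}{self.n2.value}"


def all_doublets() -> tuple[Doublet, ...]:
    """The 16 doublets, row-major in U, C, A, G order (N1 outer, N2 inner)."""
    return tuple(
        Doublet(Base(a), Base(b)) for a in BASE_ORDER for b in BASE_ORDER
    )


def anticodon_bases(d: Doublet) -> tuple[Base, Base]:
    """Anticodon bases (N36, N35) that read this doublet.

    N36 pairs the first codon position, N35 the second (antiparallel
    pairing), so each is the WC complement of its codon partner.
    """
    return complement(d.n1), complement(d.n2)


def permute_first_position(d: Doublet) -> Doublet:
    """Swap A<->U or G<->C at the first position only (involutive).

    These permutations relate doublets whose hydrogen-bond pattern is
    identical: both the WC bond count of N36-N1 and the A-minor contact
    count of the decoding-center adenosine are preserved.
    """
    return Doublet(complement(d.n1), d.n2)


class DegeneracyFamily(enum.Enum):
    """Box-level degeneracy: split (2x|2x) or fully synonymous (4x)."""

    TWO_FOLD = "two-fold"
    FOUR_FOLD = "four-fold"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


@dataclass(frozen=True)
class CodeTable:
    """A complete doublet -> degeneracy-family assignment.

    ``annotations`` optionally carries amino-acid labels per doublet
    (e.g. ``"Phe/Leu"``) for rendering; they play no role in the model.
    """

    id: str
    entries: Mapping[Doublet, DegeneracyFamily]
    annotations: Mapping[Doublet, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(all_doublets()) - set(self.entries)
        if missing:
            names = ", ".join(sorted(str(d) for d in missing))
            raise ValueError(f"code table {self.id!r} incomplete; missing {names}")

    def __getitem__(self, d: Doublet) -> DegeneracyFamily:
        return self.entries[d]

    def family_counts(self) -> dict[DegeneracyFamily, int]:
        counts = {DegeneracyFamily.TWO_FOLD: 0, DegeneracyFamily.FOUR_FOLD: 0}
        for fam in self.entries.values():
            counts[fam] += 1
        return counts

    def to_tsv(self) -> str:
        """Serialize as TSV: doublet, family, annotation columns."""
        lines = ["doublet\tfamily\tannotation"]
        for d in all_doublets():
            lines.append(
                f"{d}\t{self.entries[d].value}\t{self.annotations.get(d, '')}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, id: str = "custom") -> "CodeTable":
        rows = [ln for ln in text.splitlines() if ln.strip()]
        header = rows[0].split("\t")
        if header[:2] != ["doublet", "family"]:
            raise ValueError("TSV header must start with: doublet, family")
        entries: dict[Doublet, DegeneracyFamily] = {}
        annotations: dict[Doublet, str] = {}
        for ln in rows[1:]:
            parts = ln.split("\t")
            d = Doublet.parse(parts[0])
            entries[d] = DegeneracyFamily(parts[1])
            if len(parts) > 2 and parts[2]:
                annotations[d] = parts[2]
        return cls(id=id, entries=entries, annotations=annotations)


def _mito_table() -> CodeTable:
    # Yeast/human mitochondrial code at box level: 8 split boxes, 8
    # four-fold boxes.  The AG box is Ser/Arg in yeast mitochondria and
    # Ser/stop in human; both are split, so the family assignment is
    # shared and only the annotation differs (yeast shown).
    two_fold = {"UU", "UA", "UG", "CA", "AU", "AA", "AG", "GA"}
    entries = {
        d: (
            DegeneracyFamily.TWO_FOLD
            if str(d) in two_fold
            else DegeneracyFamily.FOUR_FOLD
        )
        for d in all_doublets()
    }
    annotations = {
        Doublet.parse(k): v
        for k, v in {
            "UU": "Phe/Leu", "UC": "Ser", "UA": "Tyr/stop", "UG": "Cys/Trp",
            "CU": "Leu", "CC": "Pro", "CA": "His/Gln", "CG": "Arg",
            "AU": "Ile/Met", "AC": "Thr", "AA": "Asn/Lys", "AG": "Ser/Arg",
            "GU": "Val", "GC": "Ala", "GA": "Asp/Glu", "GG": "Gly",
        }.items()
    }
    return CodeTable(id="mito-yeast-human", entries=entries, annotations=annotations)


#: Built-in yeast/human mitochondrial degeneracy table (box level).
MITOCHONDRIAL = _mito_table()

_TABLES = {"mito-yeast-human": MITOCHONDRIAL, "mito": MITOCHONDRIAL}


def get_code_table(table_id: str) -> CodeTable:
    """Look up a built-in code table by id (``mito`` / ``mito-yeast-human``)."""
    try:
        return _TABLES[table_id]
    except KeyError:
        raise KeyError(
            f"unknown code table {table_id!r}; built-ins: {sorted(set(_TABLES))}"
        ) from None


def known_degeneracy(d: Doublet, table: CodeTable | str = MITOCHONDRIAL) -> DegeneracyFamily:
    """Reference degeneracy family of a doublet in a code table."""
    if isinstance(table, str):
        table = get_code_table(table)
    return table[d]
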