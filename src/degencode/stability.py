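"""Hydrogen-bond stability model of codon-doublet degeneracy.

The stability of the Watson-Crick geometry of the second anticodon-codon
base pair (N35-N2) during tRNA sampling is scored by counting hydrogen
bonds from three structural parameters:

* **P1** - WC hydrogen bonds of the first base pair N36-N1 (2 for A-U,
  3 for G-C);
* **P2** - WC hydrogen bonds of the second base pair N35-N2 itself;
* **P3** - the strong U33 2'OH -> N35 bond, present only when N35 is a
  purine (i.e. when the second codon base is a pyrimidine).

Their sum S classifies each of the 16 N1N2 doublets: S <= 5 gives a
two-fold degenerate box (wobble only at the third position), S > 5 a
four-fold box (superwobble possible).  On top of the Lagerkvist sum the
decoding-center adenosine A1493 docks into the minor groove of N36-N1 as
a type-I A-minor motif, adding 3 hydrogen bonds on an A-U first pair and
4 on a G-C first pair, which raises the total stabilizing count to the
7-11 range and makes each stability level step worth either one local
bond or two bonds on the neighboring triple base pair.  The A1492
type-II contacts are excluded from all counts: that residue is engaged
only about half of the time during sampling and is treated
qualitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

from .code import (
    MITOCHONDRIAL,
    Base,
    CodeTable,
    DegeneracyFamily,
    Doublet,
    all_doublets,
    complement,
    is_purine,
    permute_first_position,
)

__all__ = [
    "HBondProfile",
    "DegeneracyTable",
    "AlphabetSpec",
    "RNA_ALPHABET",
    "wc_pair_bonds",
    "u33_bond",
    "a_minor_bonds",
    "profile",
    "classify",
    "predict_table",
    "symmetry_check",
    "configurations",
    "family_count",
    "variant_code",
    "S_THRESHOLD",
]

#: Two-fold / four-fold boundary of the hydrogen-bond sum (S <= 5 is two-fold).
S_THRESHOLD = 5

_WC_BONDS = {
    (Base.G, Base.C): 3,
    (Base.C, Base.G): 3,
    (Base.A, Base.U): 2,
    (Base.U, Base.A): 2,
}


def wc_pair_bonds(b1: Base, b2: Base) -> int:
    """Hydrogen-bond count of a Watson-Crick pair (3 for G-C, 2 for A-U).

    Non-complementary pairs (including the G-U wobble) raise: the
    stability model is defined only where positions 1 and 2 are WC.
    """
    try:
        return _WC_BONDS[(b1, b2)]
    except KeyError:
        raise ValueError(f"{b1.value}-{b2.value} is not a Watson-Crick pair") from None


def u33_bond(n2: Base) -> int:
    """P3: 1 iff the anticodon base reading n2 (N35 = complement) is a purine."""
    return 1 if is_purine(complement(n2)) else 0


def a_minor_bonds(n1: Base) -> int:
    """Type-I A-minor hydrogen bonds of A1493 with the first base pair.

    3 bonds on an A-U (or U-A) pair, 4 on a G-C (or C-G) pair; the count
    depends only on the pair type, so it is invariant under A1<->U1 and
    G1<->C1 permutations.  The C36-G1 value rests on the symmetry of the
    guanine amino group at the center of the pair (no deposited structure
    shows this configuration); it is surfaced via ``A_MINOR_ASSUMED``.
    """
    return 4 if n1 in (Base.G, Base.C) else 3


#: Doublets whose A-minor count is an inference by symmetry, not an
#: observed structure (first pair C36-G1, i.e. codons starting with G).
A_MINOR_ASSUMED = frozenset({Base.G})


@dataclass(frozen=True)
class HBondProfile:
    """Per-doublet hydrogen-bond decomposition.

    ``s = p1 + p2 + p3`` is the Lagerkvist sum; ``total = s + a_minor``
    adds the A1493 A-minor bonds; ``level = s - 3`` is the four-step
    stability ladder of the N35-N2 WC geometry.
    """

    p1: int
    p2: int
    p3: int
    a_minor: int

    def __post_init__(self) -> None:
        if self.p1 not in (2, 3) or self.p2 not in (2, 3):
            raise ValueError("WC bond counts must be 2 or 3")
        if self.p3 not in (0, 1):
            raise ValueError("P3 must be 0 or 1")
        if self.a_minor not in (3, 4):
            raise ValueError("A-minor bond count must be 3 or 4")

    @property
    def s(self) -> int:
        return self.p1 + self.p2 + self.p3

    @property
    def total(self) -> int:
        return self.s + self.a_minor

    @property
    def level(self) -> int:
        return self.s - 3


def profile(d: Doublet) -> HBondProfile:
    """Full hydrogen-bond decomposition of a doublet."""
    n36, n35 = complement(d.n1), complement(d.n2)
    return HBondProfile(
        p1=wc_pair_bonds(n36, d.n1),
        p2=wc_pair_bonds(n35, d.n2),
        p3=u33_bond(d.n2),
        a_minor=a_minor_bonds(d.n1),
    )


def classify(d: Doublet) -> DegeneracyFamily:
    """S-rule classification: two-fold iff S <= 5, four-fold iff S > 5."""
    if profile(d).s <= S_THRESHOLD:
        return DegeneracyFamily.TWO_FOLD
    return DegeneracyFamily.FOUR_FOLD


def symmetry_check(d: Doublet) -> bool:
    """True iff the profile is unchanged by the A1<->U1 / G1<->C1 permutation."""
    return profile(d) == profile(permute_first_position(d))


def configurations(level: int) -> set[tuple[int, int, int]]:
    """Distinct (P1, P2, P3) configurations realizing a stability level.

    Level ``n`` requires ``p1 + p2 + p3 = n + 3``; levels 1 and 4 are
    unique while levels 2 and 3 are three-fold degenerate (one local
    bond is interchangeable with one first-pair WC bond, which drags the
    A-minor count along).
    """
    if not 1 <= level <= 4:
        raise ValueError(f"stability level must be in [1, 4], got {level}")
    return {
        (p1, p2, p3)
        for p1, p2, p3 in product((2, 3), (2, 3), (0, 1))
        if p1 + p2 + p3 == level + 3
    }


@dataclass(frozen=True)
class DegeneracyTable:
    """Model prediction over all 16 doublets, optionally scored against a reference."""

    rows: tuple[tuple[Doublet, HBondProfile, DegeneracyFamily], ...]
    reference: CodeTable | None = None

    def __post_init__(self) -> None:
        seen = [d for d, _, _ in self.rows]
        if len(seen) != 16 or len(set(seen)) != 16:
            raise ValueError("a degeneracy table needs the 16 distinct doublets")

    @property
    def agreement(self) -> int | None:
        """Number of doublets whose predicted family matches the reference."""
        if self.reference is None:
            return None
        return sum(
            1 for d, _, fam in self.rows if self.reference[d] == fam
        )

    def family(self, d: Doublet) -> DegeneracyFamily:
        for dd, _, fam in self.rows:
            if dd == d:
                return fam
        raise KeyError(str(d))

    def count(self, kind: DegeneracyFamily) -> int:
        return sum(1 for _, _, fam in self.rows if fam == kind)

    def totals_range(self) -> tuple[int, int]:
        totals = [p.total for _, p, _ in self.rows]
        return min(totals), max(totals)

    def assumed_flags(self) -> dict[Doublet, bool]:
        """Doublets whose A-minor count is inferred by symmetry (footnote flag)."""
        return {d: d.n1 in A_MINOR_ASSUMED for d, _, _ in self.rows}


def predict_table(reference: CodeTable | None = MITOCHONDRIAL) -> DegeneracyTable:
    """Run the S-rule over all 16 doublets and score against a reference."""
    rows = tuple((d, profile(d), classify(d)) for d in all_doublets())
    return DegeneracyTable(rows=rows, reference=reference)


def family_count(t: DegeneracyTable) -> int:
    """Degeneracy families implied by a table: 2 per split box, 1 per 4x box."""
    return sum(
        2 if fam == DegeneracyFamily.TWO_FOLD else 1 for _, _, fam in t.rows
    )


# ---------------------------------------------------------------------------
# Hypothetical alphabets


@dataclass(frozen=True)
class AlphabetSpec:
    """A (possibly synthetic) four-letter alphabet for the S-rule.

    ``pair_bonds`` maps each WC pair (as a 2-tuple of Base) to its
    hydrogen-bond count; it must be symmetric under strand swap and give
    every base exactly one partner.  ``purines`` lists the bases that
    trigger the U33 2'OH bond when sitting at anticodon position 35
    (default mirrors RNA: A and G).
    """

    pair_bonds: Mapping[tuple[Base, Base], int]
    purines: frozenset[Base] = frozenset({Base.A, Base.G})

    def __post_init__(self) -> None:
        partners: dict[Base, Base] = {}
        for (b1, b2), n in self.pair_bonds.items():
            if self.pair_bonds.get((b2, b1)) != n:
                raise ValueError(
                    f"pair_bonds not symmetric for {b1.value}-{b2.value}"
                )
            if partners.setdefault(b1, b2) != b2:
                raise ValueError(f"base {b1.value} has more than one WC partner")
        if set(partners) != set(Base):
            raise ValueError("every base needs exactly one WC partner")

    def partner(self, b: Base) -> Base:
        for (b1, b2) in self.pair_bonds:
            if b1 == b:
                return b2
        raise KeyError(b)

    @classmethod
    def uniform(cls, bonds: int, purines: Iterable[Base] = (Base.A, Base.G)) -> "AlphabetSpec":
        """All four WC pairs carry the same bond count (A:U and G:C pairing)."""
        pb = {
            (Base.A, Base.U): bonds,
            (Base.U, Base.A): bonds,
            (Base.G, Base.C): bonds,
            (Base.C, Base.G): bonds,
        }
        return cls(pair_bonds=pb, purines=frozenset(purines))


#: Canonical RNA alphabet: G-C pairs 3 bonds, A-U pairs 2, A/G purines.
RNA_ALPHABET = AlphabetSpec(
    pair_bonds={
        (Base.A, Base.U): 2,
        (Base.U, Base.A): 2,
        (Base.G, Base.C): 3,
        (Base.C, Base.G): 3,
    }
)


def variant_code(spec: AlphabetSpec) -> tuple[DegeneracyTable, int]:
    """Re-apply the S-rule under substituted pair-bond counts.

    Returns the predicted table and the number of amino acids
    unambiguously encodable when one degeneracy family is reserved for
    the stop function (``family_count - 1``).  With the canonical RNA
    spec this yields 24 families / 23 amino acids; with an all-weak
    (2-bond) alphabet every box is two-fold, giving 32 families / 31
    amino acids.
    """
    rows = []
    for d in all_doublets():
        n36, n35 = spec.partner(d.n1), spec.partner(d.n2)
        p1 = spec.pair_bonds[(n36, d.n1)]
        p2 = spec.pair_bonds[(n35, d.n2)]
        p3 = 1 if n35 in spec.purines else 0
        s = p1 + p2 + p3
        fam = (
            DegeneracyFamily.TWO_FOLD if s <= S_THRESHOLD else DegeneracyFamily.FOUR_FOLD
        )
        # A-minor count tracks the first-pair bond count as in RNA
        # (one extra minor-groove acceptor on a 3-bond pair).
        a_minor = 4 if p1 == 3 else 3
        rows.append((d, HBondProfile(p1=p1, p2=p2, p3=p3, a_minor=a_minor), fam))
    table = DegeneracyTable(rows=tuple(rows), reference=None)
    return table, family_count(table) - 1
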