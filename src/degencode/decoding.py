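"""Rule-based simulation of evolutionary decoding regimes and processivity.

Three regimes bracket the proposed history of the decoding center:

* ``STAGE0_GNC`` -- no decoding center.  Default tolerance is strict WC
  at all three positions; a selectable variant additionally accepts a
  single G.U wobble pair at any one position (loosely structured
  anticodon loops allowed occasional wobble anywhere).
* ``TRANSITION1_SUPERWOBBLE`` -- helix h44 (A1493/A1492) present: WC
  required at positions 1-2, any pair accepted at the third position
  (all boxes effectively four-fold).
* ``MODERN`` -- full decoding center: WC at positions 1-2; the third
  position follows the doublet's degeneracy family (WC plus G34.U3 /
  U34.G3 wobble in two-fold boxes, any pair in four-fold boxes).

A message is translated 5'->3'; the first codon with no admissible tRNA
stalls the ribosome, and processivity is the translated prefix
fraction.  The regimes are nested -- every codon decodable under
STAGE0-strict is decodable under MODERN, and every MODERN-decodable
codon under TRANSITION1 -- so processivity is monotone in that order.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .code import Base, CodeTable, DegeneracyFamily, Doublet, complement
from .stability import DegeneracyTable, predict_table
from .synthetic import Message, MessageSpec, make_messages

__all__ = [
    "Regime",
    "Anticodon",
    "TRNASet",
    "TranslationOutcome",
    "SimConfig",
    "SimResult",
    "pairing_allowed",
    "translate",
    "simulate",
    "cognate_trna_set",
    "full_coverage_trna_set",
]


class Regime(enum.Enum):
    STAGE0_GNC = "stage0-gnc"
    TRANSITION1_SUPERWOBBLE = "transition1-superwobble"
    MODERN = "modern"


_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}
#: Third-position pairs accepted in a two-fold box under the modern
#: regime: WC plus the classic wobble pairs (reads stay within the
#: R-ending or Y-ending half of the box).
_MODERN_TWOFOLD_34 = _WC | _GU


@dataclass(frozen=True)
class Anticodon:
    """Anticodon bases at positions 34, 35, 36 (34 reads codon position 3)."""

    n34: str
    n35: str
    n36: str

    def __post_init__(self) -> None:
        for b in (self.n34, self.n35, self.n36):
            Base.parse(b)

    @property
    def intended_doublet(self) -> Doublet:
        """The codon doublet this tRNA is assigned to (WC at positions 1-2)."""
        return Doublet(
            complement(Base.parse(self.n36)), complement(Base.parse(self.n35))
        )

    def __str__(self) -> str:
        return f"{self.n34}{self.n35}{self.n36}"


@dataclass(frozen=True)
class TRNASet:
    """Available anticodons (order matters: it is the decoding tie-break)."""

    anticodons: tuple[Anticodon, ...]

    def __post_init__(self) -> None:
        if not self.anticodons:
            raise ValueError("tRNA set must be non-empty")

    @classmethod
    def from_tsv(cls, text: str) -> "TRNASet":
        rows = [ln for ln in text.splitlines() if ln.strip()]
        if rows[0].split("\t")[0] != "anticodon_34_35_36":
            raise ValueError("TSV header must start with anticodon_34_35_36")
        acs = []
        for ln in rows[1:]:
            parts = ln.split("\t")
            enabled = parts[1].strip().lower() if len(parts) > 1 else "true"
            if enabled in ("1", "true", "yes"):
                a = parts[0].strip().upper()
                acs.append(Anticodon(a[0], a[1], a[2]))
        return cls(anticodons=tuple(acs))

    def to_tsv(self) -> str:
        lines = ["anticodon_34_35_36\tenabled"]
        lines += [f"{ac}\ttrue" for ac in self.anticodons]
        return "\n".join(lines) + "\n"


def cognate_trna_set(codons: Iterable[str]) -> TRNASet:
    """One exactly-complementary anticodon per distinct codon."""
    seen: list[Anticodon] = []
    for codon in codons:
        ac = Anticodon(
            n34=complement(Base.parse(codon[2])).value,
            n35=complement(Base.parse(codon[1])).value,
            n36=complement(Base.parse(codon[0])).value,
        )
        if ac not in seen:
            seen.append(ac)
    return TRNASet(anticodons=tuple(seen))


def full_coverage_trna_set() -> TRNASet:
    """16 anticodons, one per doublet, with U34 (the superwobble base)."""
    acs = []
    for d in (Doublet(Base(a), Base(b)) for a in "UCAG" for b in "UCAG"):
        acs.append(
            Anticodon(
                n34="U",
                n35=complement(d.n2).value,
                n36=complement(d.n1).value,
            )
        )
    return TRNASet(anticodons=tuple(acs))


def _is_wc(a: str, c: str) -> bool:
    return (a, c) in _WC


def pairing_allowed(
    anticodon: Anticodon,
    codon: str,
    regime: Regime,
    code: DegeneracyTable | None = None,
    stage0_tolerance: str = "strict",
) -> bool:
    """Regime predicate: may this anticodon decode this codon?

    ``stage0_tolerance``: ``"strict"`` (WC everywhere, default) or
    ``"one-gu"`` (additionally accept a single G.U pair at any one
    position).  ``code`` (the doublet degeneracy table) is required for
    the modern regime.
    """
    n1, n2, n3 = codon[0], codon[1], codon[2]
    pairs = (
        (anticodon.n36, n1),
        (anticodon.n35, n2),
        (anticodon.n34, n3),
    )
    if regime is Regime.STAGE0_GNC:
        if stage0_tolerance == "strict":
            return all(p in _WC for p in pairs)
        if stage0_tolerance == "one-gu":
            non_wc = [p for p in pairs if p not in _WC]
            return len(non_wc) == 0 or (
                len(non_wc) == 1 and non_wc[0] in _GU
            )
        raise ValueError(f"unknown stage0 tolerance {stage0_tolerance!r}")
    # both later regimes require WC at positions 1-2
    if pairs[0] not in _WC or pairs[1] not in _WC:
        return False
    if regime is Regime.TRANSITION1_SUPERWOBBLE:
        return True
    if regime is Regime.MODERN:
        if code is None:
            raise ValueError("the modern regime needs a degeneracy table")
        doublet = Doublet(Base.parse(n1), Base.parse(n2))
        if code.family(doublet) is DegeneracyFamily.FOUR_FOLD:
            return True
        return pairs[2] in _MODERN_TWOFOLD_34
    raise ValueError(f"unknown regime {regime!r}")  # pragma: no cover


@dataclass(frozen=True)
class TranslationOutcome:
    """Per-message result: decoded prefix, stall point, miscoding count."""

    decoded_by: tuple[int, ...]  # tRNA index per decoded codon
    stall_index: int | None  # codon index of the first stall, None if complete
    fraction: float
    miscoded: int

    @property
    def complete(self) -> bool:
        return self.stall_index is None


def _decoder_map(
    trnas: TRNASet,
    regime: Regime,
    code: DegeneracyTable | None,
    stage0_tolerance: str,
) -> dict[str, int | None]:
    """Chosen tRNA index (or None) for each of the 64 codons.

    Priority: most WC positions first (exact WC beats wobble), then
    input order.
    """
    table: dict[str, int | None] = {}
    for n1 in "UCAG":
        for n2 in "UCAG":
            for n3 in "UCAG":
                codon = n1 + n2 + n3
                best: tuple[int, int] | None = None  # (-wc_count, index)
                for i, ac in enumerate(trnas.anticodons):
                    if not pairing_allowed(
                        ac, codon, regime, code, stage0_tolerance
                    ):
                        continue
                    wc = sum(
                        1
                        for p in (
                            (ac.n36, n1),
                            (ac.n35, n2),
                            (ac.n34, n3),
                        )
                        if p in _WC
                    )
                    key = (-wc, i)
                    if best is None or key < best:
                        best = key
                table[codon] = None if best is None else best[1]
    return table


def translate(
    msg: Message,
    trnas: TRNASet,
    regime: Regime,
    code: DegeneracyTable | None = None,
    stage0_tolerance: str = "strict",
    _decoder: dict[str, int | None] | None = None,
) -> TranslationOutcome:
    """Scan codons 5'->3' until the first codon with no admissible tRNA."""
    decoder = (
        _decoder
        if _decoder is not None
        else _decoder_map(trnas, regime, code, stage0_tolerance)
    )
    decoded: list[int] = []
    miscoded = 0
    stall: int | None = None
    for i, codon in enumerate(msg.codons):
        idx = decoder[codon]
        if idx is None:
            stall = i
            break
        decoded.append(idx)
        ac = trnas.anticodons[idx]
        if str(ac.intended_doublet) != codon[:2]:
            miscoded += 1
    n = len(msg.codons)
    fraction = 1.0 if stall is None else stall / n
    return TranslationOutcome(
        decoded_by=tuple(decoded),
        stall_index=stall,
        fraction=fraction,
        miscoded=miscoded,
    )


@dataclass(frozen=True)
class SimConfig:
    """Processivity-simulation configuration (seed is mandatory)."""

    n_messages: int
    length: int
    regime: Regime
    trna_set: TRNASet
    seed: int
    code: DegeneracyTable | None = None
    source_code: str = "GNC"
    third_pos_mutation_rate: float = 0.0
    all_pos_mutation_rate: float = 0.0
    stage0_tolerance: str = "strict"
    ancestor: tuple[str, ...] | None = None


@dataclass(frozen=True)
class SimResult:
    """Aggregate over messages.  CI half-widths are normal-approximation
    binomial (1.96 * sqrt(p(1-p)/n)) for the message-level rates."""

    processivity: float
    full_translation_rate: float
    miscoding_rate: float
    n: int
    seed: int
    full_translation_ci: float
    processivity_sem: float


def simulate(cfg: SimConfig) -> SimResult:
    """Generate mutated messages, translate each, aggregate the outcome."""
    code = cfg.code
    if code is None and cfg.regime is Regime.MODERN:
        code = predict_table()
    messages = make_messages(
        MessageSpec(
            n=cfg.n_messages,
            length=cfg.length,
            source_code=cfg.source_code,
            m3=cfg.third_pos_mutation_rate,
            m_all=cfg.all_pos_mutation_rate,
            seed=cfg.seed,
            ancestor=cfg.ancestor,
        )
    )
    decoder = _decoder_map(cfg.trna_set, cfg.regime, code, cfg.stage0_tolerance)
    fractions = []
    full = 0
    decoded_codons = 0
    miscoded = 0
    for msg in messages:
        out = translate(
            msg, cfg.trna_set, cfg.regime, code, cfg.stage0_tolerance, _decoder=decoder
        )
        fractions.append(out.fraction)
        full += out.complete
        decoded_codons += len(out.decoded_by)
        miscoded += out.miscoded
    n = len(messages)
    mean_frac = sum(fractions) / n
    var = sum((f - mean_frac) ** 2 for f in fractions) / max(n - 1, 1)
    p_full = full / n
    return SimResult(
        processivity=mean_frac,
        full_translation_rate=p_full,
        miscoding_rate=(miscoded / decoded_codons) if decoded_codons else 0.0,
        n=n,
        seed=cfg.seed,
        full_translation_ci=1.96 * math.sqrt(p_full * (1 - p_full) / n),
        processivity_sem=math.sqrt(var / n),
    )
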