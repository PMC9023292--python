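"""Synthetic inputs: coordinate fixtures, energy/volume tables, mutated messages.

Everything here is a pure function of its spec (including the seed), so
fixtures are regenerated at run time instead of being shipped as data.
The coordinate fixtures are geometric scaffolds -- named donor/acceptor
atoms placed at prescribed distances, not stereochemically valid
nucleotides: they exercise the distance-measurement logic, not
chemistry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .code import Base
from .geometry import AtomRef, ContactSpec
from .kinetics import EnergyVolumeTables

__all__ = [
    "FixtureSpec",
    "TableSpec",
    "MessageSpec",
    "Message",
    "make_fixture_structure",
    "make_energy_volume_tables",
    "make_messages",
    "write_fasta",
    "read_fasta",
    "GNC_CODONS",
    "source_codons",
]

# ---------------------------------------------------------------------------
# Coordinate fixtures


@dataclass(frozen=True)
class FixtureSpec:
    """Prescription for a synthetic coordinate file.

    ``contacts`` lists (label, target donor-acceptor distance in
    angstroms).  ``decoy_atoms`` adds unrelated atoms so lookups must
    actually resolve chain/residue/atom.  A non-None ``seed`` applies a
    random rigid-body transform (distances are invariant).
    """

    contacts: tuple[tuple[str, float], ...]
    decoy_atoms: int = 12
    seed: int | None = None

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.contacts]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate contact labels in fixture spec")
        if not self.contacts:
            raise ValueError("fixture spec needs at least one contact")
        for lab, dist in self.contacts:
            if not (math.isfinite(dist) and dist > 0):
                raise ValueError(f"contact {lab!r}: distance must be > 0, got {dist}")


_DONOR_ATOM = "N1"
_ACCEPTOR_ATOM = "O2'"
_SPACING = 20.0  # between contact pairs, well beyond any H-bond length


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix gives a Haar-random orthogonal matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def make_fixture_structure(
    spec: FixtureSpec, path: str | Path | None = None
) -> tuple[gemmi.Structure, list[ContactSpec]]:
    """Build (and optionally write as PDB) a fixture realizing the spec.

    Contact ``i`` is residue ``i+1``: the donor atom sits on chain A,
    the acceptor on chain B at exactly the target distance.  Decoys go
    on chain X, rejected if within 1.5 A of any placed atom.  Returns
    the structure and the contact list that measures it.
    """
    rng = np.random.default_rng(spec.seed if spec.seed is not None else 0)

    coords: list[tuple[str, int, str, np.ndarray]] = []  # chain, resi, atom, xyz
    contact_specs: list[ContactSpec] = []
    for i, (label, dist) in enumerate(spec.contacts):
        resi = i + 1
        donor_xyz = np.array([_SPACING * i, 0.0, 0.0])
        acceptor_xyz = donor_xyz + np.array([dist, 0.0, 0.0])
        coords.append(("A", resi, _DONOR_ATOM, donor_xyz))
        coords.append(("B", resi, _ACCEPTOR_ATOM, acceptor_xyz))
        contact_specs.append(
            ContactSpec(
                label=label,
                donor=AtomRef(chain="A", resi=resi, atom=_DONOR_ATOM),
                acceptor=AtomRef(chain="B", resi=resi, atom=_ACCEPTOR_ATOM),
            )
        )

    placed = np.array([c[3] for c in coords])
    n_placed = 0
    attempts = 0
    while n_placed < spec.decoy_atoms and attempts < 10_000:
        attempts += 1
        cand = rng.uniform(
            low=(-10.0, 5.0, -10.0),
            high=(_SPACING * len(spec.contacts) + 10.0, 30.0, 10.0),
        )
        if np.min(np.linalg.norm(placed - cand, axis=1)) < 1.5:
            continue
        n_placed += 1
        coords.append(("X", n_placed, "C1", cand))
        placed = np.vstack([placed, cand])

    if spec.seed is not None:
        rot = _random_rotation(rng)
        shift = rng.uniform(-50.0, 50.0, size=3)
        coords = [(c, r, a, rot @ xyz + shift) for c, r, a, xyz in coords]

    st = gemmi.Structure()
    st.name = "synthetic-fixture"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for chain_name, resi, atom_name, xyz in coords:
        chain = chains.get(chain_name)
        if chain is None:
            chain = gemmi.Chain(chain_name)
            chains[chain_name] = chain
        res = None
        for existing in chain:
            if existing.seqid.num == resi:
                res = existing
                break
        if res is None:
            res = gemmi.Residue()
            res.name = "FIX"
            res.seqid = gemmi.SeqId(resi, " ")
            chain.add_residue(res)
            res = chain[len(chain) - 1]
        atom = gemmi.Atom()
        atom.name = atom_name
        atom.element = gemmi.Element(atom_name[0])
        atom.occ = 1.0
        atom.pos = gemmi.Position(*map(float, xyz))
        res.add_atom(atom)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()

    if path is not None:
        st.write_pdb(str(path))
    return st, contact_specs


# ---------------------------------------------------------------------------
# Energy / volume tables

#: Three-letter amino-acid names used for species labels (n <= 20).
_AA_NAMES = (
    "gly", "ala", "ser", "cys", "asp", "pro", "asn", "thr", "glu", "val",
    "gln", "his", "met", "ile", "leu", "lys", "arg", "phe", "tyr", "trp",
)


@dataclass(frozen=True)
class TableSpec:
    """Log-linear -dG0 vs volume relation with Gaussian noise.

    Defaults put volumes in the amino-acid van der Waals range
    (60-230 A^3) and duplex stabilities around 1-3 kcal/mol, the scale
    of trinucleotide anticodon-codon duplexes.
    """

    n: int = 20
    slope: float = 0.01  # kcal/mol per A^3
    intercept: float = 0.5  # kcal/mol
    noise_sd: float = 0.0
    seed: int = 0
    volume_range: tuple[float, float] = (60.0, 230.0)

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need n >= 3 species")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_energy_volume_tables(spec: TableSpec) -> EnergyVolumeTables:
    """Sample volumes and set -dG0 = intercept + slope*volume + noise."""
    rng = np.random.default_rng(spec.seed)
    if spec.n <= len(_AA_NAMES):
        species = list(_AA_NAMES[: spec.n])
    else:
        species = [f"sp{i:03d}" for i in range(spec.n)]
    volumes = rng.uniform(*spec.volume_range, size=spec.n)
    stability = spec.intercept + spec.slope * volumes
    if spec.noise_sd > 0:
        stability = stability + rng.normal(0.0, spec.noise_sd, size=spec.n)
    return EnergyVolumeTables(
        dg0={s: float(-st) for s, st in zip(species, stability)},
        volume={s: float(v) for s, v in zip(species, volumes)},
    )


# ---------------------------------------------------------------------------
# Mutated messages

#: The hypothesized primordial GNC codon repertoire.
GNC_CODONS = ("GUC", "GCC", "GAC", "GGC")

_SOURCE_CODES = {
    "GNC": GNC_CODONS,
    "NNN": tuple(
        a + b + c for a in "UCAG" for b in "UCAG" for c in "UCAG"
    ),
}


def source_codons(code_id: str) -> tuple[str, ...]:
    try:
        return _SOURCE_CODES[code_id]
    except KeyError:
        raise KeyError(
            f"unknown source code {code_id!r}; built-ins: {sorted(_SOURCE_CODES)}"
        ) from None


@dataclass(frozen=True)
class Message:
    """A codon sequence with its mutational provenance."""

    codons: tuple[str, ...]
    ancestor: tuple[str, ...]
    mutated_positions: tuple[int, ...]  # 0-based nucleotide positions

    @property
    def sequence(self) -> str:
        return "".join(self.codons)


@dataclass(frozen=True)
class MessageSpec:
    """Mutated-message generator parameters.

    ``m3`` is the per-third-position substitution rate, ``m_all`` an
    optional rate applied independently at every position (so the
    effective third-position rate is 1-(1-m3)(1-m_all)).  The
    substituted base is uniform over the three alternatives.  A fixed
    ``ancestor`` (codon tuple) replaces random ancestor draws.
    """

    n: int = 100
    length: int = 50
    source_code: str = "GNC"
    m3: float = 0.0
    m_all: float = 0.0
    seed: int = 0
    ancestor: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for name, rate in (("m3", self.m3), ("m_all", self.m_all)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.n < 1 or self.length < 1:
            raise ValueError("n and length must be >= 1")


_BASES = "ACGU"


def make_messages(spec: MessageSpec) -> list[Message]:
    """Generate mutated messages; pure function of the spec (bit-reproducible)."""
    rng = np.random.default_rng(spec.seed)
    if spec.ancestor is not None:
        for codon in spec.ancestor:
            if len(codon) != 3 or any(b not in _BASES for b in codon):
                raise ValueError(f"invalid ancestor codon {codon!r}")
    else:
        codon_pool = source_codons(spec.source_code)

    messages = []
    for _ in range(spec.n):
        if spec.ancestor is not None:
            ancestor = tuple(spec.ancestor)
        else:
            idx = rng.integers(0, len(codon_pool), size=spec.length)
            ancestor = tuple(codon_pool[i] for i in idx)
        seq = list("".join(ancestor))
        mutated: list[int] = []
        for pos in range(len(seq)):
            hit = rng.random() < spec.m_all
            if pos % 3 == 2 and rng.random() < spec.m3:
                hit = True
            if hit:
                alternatives = [b for b in _BASES if b != seq[pos]]
                seq[pos] = alternatives[rng.integers(0, 3)]
                mutated.append(pos)
        codons = tuple(
            "".join(seq[i : i + 3]) for i in range(0, len(seq), 3)
        )
        messages.append(
            Message(codons=codons, ancestor=ancestor, mutated_positions=tuple(mutated))
        )
    return messages


def write_fasta(messages: Sequence[Message], path: str | Path) -> None:
    """Write messages as RNA FASTA; mutation positions go in the description."""
    records = []
    for i, msg in enumerate(messages):
        mut = ",".join(map(str, msg.mutated_positions)) or "-"
        records.append(
            SeqRecord(
                Seq(msg.sequence),
                id=f"msg{i:05d}",
                description=f"mutations={mut}",
            )
        )
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[Message]:
    """Read messages back; provenance is restored from the description."""
    messages = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("T", "U")
        if len(seq) % 3:
            raise ValueError(f"{rec.id}: sequence length not a multiple of 3")
        codons = tuple(seq[i : i + 3] for i in range(0, len(seq), 3))
        mut: tuple[int, ...] = ()
        for tokens in rec.description.split():
            if tokens.startswith("mutations=") and tokens != "mutations=-":
                mut = tuple(int(x) for x in tokens[len("mutations="):].split(","))
        messages.append(Message(codons=codons, ancestor=codons, mutated_positions=mut))
    return messages
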