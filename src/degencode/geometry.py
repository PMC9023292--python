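"""Donor-acceptor distance measurement on mmCIF/PDB structures.

Hydrogen bonds are proxied by heavy-atom donor-acceptor distances.
Contacts are declared as data (``ContactSpec``), resolved against one
model of a structure under an explicit altloc policy, and reported at
the 0.1-angstrom precision of the source measurements (round half away
from zero).  Built-in contact maps for the ribosomal decoding-center
complexes ship as packaged YAML; the atom identities in those maps are
reconstructions of the canonical type-I A-minor geometry (the original
distance sets label bonds 1/1'/2/3 without printing atom names) and are
meant to be edited, not trusted blindly.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import gemmi
import yaml

__all__ = [
    "AtomRef",
    "ContactSpec",
    "ContactMap",
    "DistanceReport",
    "load_structure",
    "distance",
    "measure_contacts",
    "builtin_contact_maps",
    "load_contact_map_yaml",
    "CONTACT_MAP_VERSION",
]


@dataclass(frozen=True)
class AtomRef:
    """One atom: chain id, author residue number, atom name, optional icode."""

    chain: str
    resi: int
    atom: str
    icode: str | None = None

    def __str__(self) -> str:
        ic = self.icode or ""
        return f"{self.chain}/{self.resi}{ic}/{self.atom}"


@dataclass(frozen=True)
class ContactSpec:
    """A labelled donor-acceptor pair."""

    label: str
    donor: AtomRef
    acceptor: AtomRef

    def __post_init__(self) -> None:
        if self.donor == self.acceptor:
            raise ValueError(f"contact {self.label!r}: donor equals acceptor")


@dataclass(frozen=True)
class ContactMap:
    """Editable contact list for one structure, with provenance note."""

    structure_id: str
    contacts: tuple[ContactSpec, ...]
    note: str = ""
    version: str = ""


@dataclass(frozen=True)
class DistanceReport:
    """Measured distances (A).  ``distances`` keeps 2 decimals internally;
    ``rounded`` and ``mean`` are at the 1-decimal reporting precision."""

    structure_id: str
    distances: dict[str, float]
    policy: dict[str, object]

    @property
    def rounded(self) -> dict[str, float]:
        return {k: _round_half_up(v, 1) for k, v in self.distances.items()}

    @property
    def mean(self) -> float:
        vals = list(self.distances.values())
        return _round_half_up(sum(vals) / len(vals), 1)


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class StructureHandle:
    """One selected model plus the policy used to resolve atoms."""

    model: gemmi.Model
    structure_id: str
    model_index: int
    altloc_policy: str


def load_structure(
    path: str | Path, model_index: int = 1, altloc_policy: str = "occupancy"
) -> StructureHandle:
    """Read an mmCIF or PDB file and select one model.

    ``model_index`` is 1-based.  ``altloc_policy``: ``"occupancy"``
    keeps the highest-occupancy alternate location (ties broken toward
    'A'); ``"first"`` keeps the first encountered.
    """
    path = Path(path)
    if altloc_policy not in ("occupancy", "first"):
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    if not 1 <= model_index <= len(st):
        raise IndexError(
            f"model index {model_index} out of range 1..{len(st)} in {path}"
        )
    return StructureHandle(
        model=st[model_index - 1],
        structure_id=st.name.lower() or path.stem.lower(),
        model_index=model_index,
        altloc_policy=altloc_policy,
    )


def _resolve(handle: StructureHandle, ref: AtomRef) -> gemmi.Atom:
    for chain in handle.model:
        if chain.name != ref.chain:
            continue
        for res in chain:
            if res.seqid.num != ref.resi:
                continue
            if ref.icode and res.seqid.icode.strip() != ref.icode:
                continue
            candidates = [a for a in res if a.name == ref.atom]
            if not candidates:
                continue
            if len(candidates) == 1 or handle.altloc_policy == "first":
                return candidates[0]
            # highest occupancy; ties toward altloc 'A'
            return sorted(
                candidates, key=lambda a: (-a.occ, a.altloc or "A")
            )[0]
    raise KeyError(f"atom not found: {ref} (model {handle.model_index})")


def distance(handle: StructureHandle, a: AtomRef, b: AtomRef) -> float:
    """Euclidean donor-acceptor distance in angstroms."""
    pa = _resolve(handle, a).pos
    pb = _resolve(handle, b).pos
    return pa.dist(pb)


def measure_contacts(
    handle: StructureHandle,
    contacts: list[ContactSpec] | tuple[ContactSpec, ...] | ContactMap,
) -> DistanceReport:
    """Measure every declared contact; unresolved refs are reported together."""
    structure_id = handle.structure_id
    if isinstance(contacts, ContactMap):
        structure_id = contacts.structure_id or structure_id
        contacts = contacts.contacts
    if not contacts:
        raise ValueError("no contacts to measure")
    distances: dict[str, float] = {}
    failures: list[str] = []
    for c in contacts:
        try:
            distances[c.label] = round(distance(handle, c.donor, c.acceptor), 2)
        except KeyError as exc:
            failures.append(str(exc))
    if failures:
        raise KeyError("unresolved contacts: " + "; ".join(failures))
    return DistanceReport(
        structure_id=structure_id,
        distances=distances,
        policy={
            "model_index": handle.model_index,
            "altloc_policy": handle.altloc_policy,
        },
    )


# ---------------------------------------------------------------------------
# Built-in contact maps

CONTACT_MAP_VERSION = "1.0"


def _parse_map(structure_id: str, payload: dict, version: str) -> ContactMap:
    contacts = []
    for entry in payload.get("contacts", []):
        contacts.append(
            ContactSpec(
                label=str(entry["label"]),
                donor=AtomRef(
                    chain=str(entry["donor"]["chain"]),
                    resi=int(entry["donor"]["resi"]),
                    atom=str(entry["donor"]["atom"]),
                    icode=entry["donor"].get("icode"),
                ),
                acceptor=AtomRef(
                    chain=str(entry["acceptor"]["chain"]),
                    resi=int(entry["acceptor"]["resi"]),
                    atom=str(entry["acceptor"]["atom"]),
                    icode=entry["acceptor"].get("icode"),
                ),
            )
        )
    return ContactMap(
        structure_id=structure_id,
        contacts=tuple(contacts),
        note=payload.get("note", ""),
        version=version,
    )


def load_contact_map_yaml(path: str | Path, structure_id: str = "custom") -> ContactMap:
    """Load a user contact map (same schema as the packaged file)."""
    payload = yaml.safe_load(Path(path).read_text())
    if "contacts" not in payload and "maps" in payload:
        raise ValueError("file looks like a multi-map bundle; pass one map")
    return _parse_map(structure_id, payload, payload.get("version", "custom"))


def builtin_contact_maps(structure_id: str) -> ContactMap:
    """Packaged default contact map for a cited decoding-center structure.

    Known ids: 5wfk (first-position mismatch -- no A-minor bonds form,
    empty map with advisory note), 5uyp, 5uyl (three A-minor contacts of
    A1493 with an A-U first pair), 1xnq (four contacts, including the
    extra 1' bond on a G-C first pair).
    """
    sid = structure_id.lower()
    data = importlib.resources.files("degencode.data").joinpath("contact_maps.yaml")
    bundle = yaml.safe_load(data.read_text())
    maps = bundle.get("maps", {})
    if sid not in maps:
        raise KeyError(
            f"no built-in contact map for {structure_id!r}; known: {sorted(maps)}"
        )
    return _parse_map(sid, maps[sid], bundle.get("version", CONTACT_MAP_VERSION))
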