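"""Structure and validation-report input/output.

Reads experimental (PDB/mmCIF) and predicted structures into a uniform
chain → residue → atom hierarchy, keeping author numbering, separating
hetero (ligand) groups from the polymer, and applying a fixed altloc
policy (highest occupancy wins; ties break alphabetically; hydrogens are
dropped everywhere). Per-residue validation tracks (RSCC from wwPDB-style
validation XML, pLDDT stored in the B-factor slot of predicted models)
are exposed as sparse author-numbered series.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "ChainModel",
    "StructureModel",
    "DomainSpan",
    "PerResidueTrack",
    "read_structure",
    "write_pdb",
    "load_plddt_track",
    "read_validation_rscc",
    "select_domain",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class AtomRecord:
    """One atom: name, element, position (Å), B-factor/pLDDT, occupancy."""

    name: str
    element: str
    coords: np.ndarray
    b_value: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")
        if self.b_value < 0:
            raise ValueError(f"atom {self.name}: negative b_value {self.b_value}")


@dataclass
class ResidueRecord:
    """One residue under author numbering with its retained atoms."""

    auth_seq: int
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)
    icode: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for a in self.atoms:
            key = (a.name, a.altloc)
            if key in seen:
                raise ValueError(
                    f"residue {self.res_name}{self.auth_seq}: duplicate atom {key}"
                )
            seen.add(key)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def backbone_complete(self) -> bool:
        names = {a.name for a in self.atoms}
        return all(n in names for n in BACKBONE_ATOMS)


@dataclass
class ChainModel:
    chain_id: str
    residues: list[ResidueRecord]
    source_kind: Literal["experimental", "predicted"] = "experimental"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"chain {self.chain_id}: empty")
        keys = [(r.auth_seq, r.icode) for r in self.residues]
        if keys != sorted(keys):
            raise ValueError(f"chain {self.chain_id}: residues not ordered by (auth_seq, icode)")

    def residue(self, auth_seq: int) -> ResidueRecord | None:
        for r in self.residues:
            if r.auth_seq == auth_seq:
                return r
        return None


@dataclass
class StructureModel:
    identifier: str
    chains: list[ChainModel]
    hetero_groups: dict[tuple[str, str, int], list[AtomRecord]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.identifier}: duplicate chain ids")

    def chain(self, chain_id: str) -> ChainModel:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"{self.identifier}: no chain {chain_id!r}")


@dataclass(frozen=True)
class DomainSpan:
    """Inclusive author-numbered residue interval naming a domain."""

    domain_name: str  # DBD | LBD | Hinge
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.domain_name}: start {self.start} > end {self.end}")

    def __contains__(self, auth_seq: int) -> bool:
        return self.start <= auth_seq <= self.end


@dataclass
class PerResidueTrack:
    metric_name: str  # RSCC | pLDDT | b_factor
    values: dict[int, float]

    def residues(self) -> list[int]:
        return sorted(self.values)


def _pick_altloc(atoms: Iterable[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy; ties resolve to the alphabetically first altloc
    return min(atoms, key=lambda a: (-a.occ, a.altloc or "~"))


def read_structure(
    path: str | Path,
    fmt: Literal["pdb", "mmcif", "auto"] = "auto",
    source_kind: Literal["experimental", "predicted"] = "experimental",
    identifier: str | None = None,
) -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    The highest-occupancy altloc is retained per atom name, hydrogens are
    dropped, hetero groups (excluding water) are separated from the
    polymer, and only the first model of multi-model files is read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        else:
            st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]

    chains: list[ChainModel] = []
    hetero: dict[tuple[str, str, int], list[AtomRecord]] = {}
    for chain in model:
        residues: list[ResidueRecord] = []
        for res in chain:
            groups: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                groups.setdefault(atom.name, []).append(atom)
            records = []
            for name in groups:
                a = _pick_altloc(groups[name])
                altloc = a.altloc if a.altloc not in ("", "\x00", None) else ""
                records.append(
                    AtomRecord(
                        name=name,
                        element=a.element.name,
                        coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        b_value=max(a.b_iso, 0.0),
                        occupancy=min(max(a.occ, 0.0), 1.0),
                        altloc=altloc,
                    )
                )
            if not records:
                continue
            if res.is_water():
                continue
            info = gemmi.find_tabulated_residue(res.name)
            is_polymer = res.entity_type == gemmi.EntityType.Polymer or (
                info is not None and (info.is_amino_acid() or info.is_nucleic_acid())
            )
            if not is_polymer:
                hetero[(chain.name, res.name, res.seqid.num)] = records
            else:
                residues.append(
                    ResidueRecord(
                        auth_seq=res.seqid.num,
                        res_name=res.name,
                        atoms=records,
                        icode=(res.seqid.icode or "").strip(),
                    )
                )
        if residues:
            residues.sort(key=lambda r: (r.auth_seq, r.icode))
            chains.append(ChainModel(chain.name, residues, source_kind=source_kind))
    if not chains:
        raise ValueError(f"{path}: no polymer residues found")
    return StructureModel(identifier or path.stem, chains, hetero)


_PDB_ATOM = (
    "ATOM  {serial:>5d} {name:<4s}{alt:1s}{res:<3s} {chain:1s}{seq:>4d}{icode:1s}   "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}\n"
)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the polymer and hetero groups as fixed-width PDB records."""
    path = Path(path)
    serial = 0
    with path.open("w") as fh:
        for chain in model.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    serial += 1
                    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                    fh.write(
                        _PDB_ATOM.format(
                            serial=serial, name=name, alt=atom.altloc or " ",
                            res=res.res_name, chain=chain.chain_id, seq=res.auth_seq,
                            icode=res.icode or " ",
                            x=atom.coords[0], y=atom.coords[1], z=atom.coords[2],
                            occ=atom.occupancy, b=atom.b_value, elem=atom.element,
                        )
                    )
            fh.write("TER\n")
        for (chain_id, res_name, seq), atoms in model.hetero_groups.items():
            for atom in atoms:
                serial += 1
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                fh.write(
                    _PDB_ATOM.format(
                        serial=serial, name=name, alt=" ", res=res_name,
                        chain=chain_id, seq=seq, icode=" ",
                        x=atom.coords[0], y=atom.coords[1], z=atom.coords[2],
                        occ=1.0, b=0.0, elem=atom.element,
                    ).replace("ATOM  ", "HETATM", 1)
                )
        fh.write("END\n")


def load_plddt_track(model: StructureModel, chain_id: str) -> PerResidueTrack:
    """Extract the per-residue pLDDT confidence track of a predicted model.

    Predicted models store raw pLDDT (0–100) in the B-factor slot; the
    track is the CA value scaled by 1/100 so it shares the RSCC range.
    Values already at or below 1 are rejected to prevent double scaling.
    """
    chain = model.chain(chain_id)
    if chain.source_kind != "predicted":
        raise ValueError(f"{model.identifier}/{chain_id}: not a predicted model")
    values: dict[int, float] = {}
    for res in chain.residues:
        ca = res.atom("CA")
        if ca is None:
            continue
        if not 0.0 <= ca.b_value <= 100.0:
            raise ValueError(
                f"residue {res.auth_seq}: b_value {ca.b_value} outside pLDDT range [0,100]"
            )
        values[res.auth_seq] = ca.b_value / 100.0
    if values and max(values.values()) <= 0.011:
        raise ValueError("values already ≤ 1: track appears scaled once already")
    return PerResidueTrack("pLDDT", values)


def read_validation_rscc(path: str | Path, chain_id: str) -> PerResidueTrack:
    """Read per-residue RSCC for one chain from a wwPDB-style validation XML.

    Residues without density statistics (no ``rscc`` attribute) are
    omitted rather than zero-filled.
    """
    tree = ET.parse(str(path))
    values: dict[int, float] = {}
    found_chain = False
    for el in tree.getroot().iter("ModelledSubgroup"):
        if el.get("chain") != chain_id:
            continue
        found_chain = True
        rscc = el.get("rscc")
        if rscc is None:
            continue
        seq = int(el.get("resnum"))
        if seq in values:
            raise ValueError(f"duplicate RSCC entry for residue {seq} in chain {chain_id}")
        values[seq] = float(rscc)
    if not found_chain:
        raise ValueError(f"{path}: chain {chain_id!r} not present in validation report")
    if not values:
        raise ValueError(f"{path}: no RSCC data for chain {chain_id!r}")
    return PerResidueTrack("RSCC", values)


def load_bfactor_track(model: StructureModel, chain_id: str) -> PerResidueTrack:
    """Per-residue CA B-factor of an experimental chain (Å²)."""
    chain = model.chain(chain_id)
    values = {
        r.auth_seq: r.atom("CA").b_value for r in chain.residues if r.atom("CA") is not None
    }
    if not values:
        raise ValueError(f"{model.identifier}/{chain_id}: no CA atoms")
    return PerResidueTrack("b_factor", values)


def select_domain(
    chain: ChainModel,
    span: DomainSpan,
    atom_mode: Literal["all", "backbone", "ca"] = "all",
) -> list[AtomRecord]:
    """Atoms of the residues inside ``span`` under the requested mode.

    ``backbone`` keeps N, CA, C, O; ``ca`` keeps CA only. Residues with an
    incomplete backbone are excluded from backbone/ca selections but kept
    for all-atom counts.
    """
    atoms: list[AtomRecord] = []
    for res in chain.residues:
        if res.auth_seq not in span:
            continue
        if atom_mode == "all":
            atoms.extend(res.atoms)
        elif atom_mode == "backbone":
            if res.backbone_complete:
                atoms.extend(a for a in res.atoms if a.name in BACKBONE_ATOMS)
        elif atom_mode == "ca":
            if res.backbone_complete:
                ca = res.atom("CA")
                if ca is not None:
                    atoms.append(ca)
        else:
            raise ValueError(f"unknown atom_mode {atom_mode!r}")
    if not atoms:
        raise ValueError(
            f"chain {chain.chain_id}: no atoms in span "
            f"{span.domain_name} {span.start}-{span.end} (mode={atom_mode})"
        )
    return atoms


def coords_array(atoms: Iterable[AtomRecord]) -> np.ndarray:
    """Stack atom coordinates into an (n, 3) array."""
    return np.array([a.coords for a in atoms], dtype=float).reshape(-1, 3)
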