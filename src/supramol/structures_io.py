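"""Macromolecular structure I/O and the geometric core types.

Chains are the unit every other module consumes: a :class:`ChainStructure`
is one polypeptide chain with ordered residues and heavy-atom coordinates.
Reading goes through gemmi (PDB and mmCIF); writing emits a multi-chain PDB
file with a JSON provenance sidecar describing how each subunit was placed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "ChainStructure",
    "RigidTransform",
    "StructureFormatError",
    "EmptyStructureError",
    "ChainIDOverflowError",
    "read_structure",
    "write_complex",
    "apply_transform",
]

#: deterministic chain-ID alphabet for written complexes (62 IDs)
CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",  # selenomethionine kept as methionine
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}
ONE_TO_THREE["X"] = "UNK"


class StructureFormatError(ValueError):
    """The file could not be parsed under the named standard."""


class EmptyStructureError(ValueError):
    """The file contains no polymer chain."""


class ChainIDOverflowError(ValueError):
    """More subunits than available chain identifiers."""


@dataclass
class AtomRecord:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), angstrom
    is_heavy: bool = True

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")
        if not self.element:
            raise ValueError("atom element must be non-empty")


@dataclass
class Residue:
    seq_index: int          # 1-based position in the chain
    aa: str                 # one-letter amino acid, X allowed
    atoms: list = field(default_factory=list)
    insertion_code: str = ""

    def __post_init__(self):
        if self.seq_index < 1:
            raise ValueError("seq_index must be >= 1")

    @property
    def has_coordinates(self) -> bool:
        return len(self.atoms) > 0

    def atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Optional[np.ndarray]:
        a = self.atom("CA")
        return a.coords if a is not None else None


@dataclass
class ChainStructure:
    chain_id: str
    residues: list                       # ordered list of Residue
    source_entry: str = ""               # structure accession, e.g. a PDB code
    source_protein: Optional[str] = None  # sequence-database accession

    def __post_init__(self):
        idx = [r.seq_index for r in self.residues]
        if any(b < a for a, b in zip(idx, idx[1:])):
            raise ValueError("residues must be ordered by seq_index")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """(n, 3) array of C-alpha coordinates; NaN rows for missing atoms."""
        out = np.full((len(self.residues), 3), np.nan)
        for i, r in enumerate(self.residues):
            ca = r.ca
            if ca is not None:
                out[i] = ca
        return out

    def heavy_atom_coords(self) -> np.ndarray:
        pts = [a.coords for r in self.residues for a in r.atoms if a.is_heavy]
        if not pts:
            return np.empty((0, 3))
        return np.vstack(pts)

    def copy(self) -> "ChainStructure":
        return ChainStructure(
            chain_id=self.chain_id,
            residues=[
                Residue(
                    r.seq_index,
                    r.aa,
                    [AtomRecord(a.name, a.element, a.coords.copy(), a.is_heavy) for a in r.atoms],
                    r.insertion_code,
                )
                for r in self.residues
            ],
            source_entry=self.source_entry,
            source_protein=self.source_protein,
        )


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R @ x + t."""

    rotation: np.ndarray     # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        rtr = self.rotation.T @ self.rotation
        if not np.allclose(rtr, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying `other` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def to_json(self) -> dict:
        return {
            "rotation": [[round(v, 12) for v in row] for row in self.rotation.tolist()],
            "translation": [round(v, 12) for v in self.translation.tolist()],
        }


def _one_letter(resname: str) -> str:
    return THREE_TO_ONE.get(resname.upper(), "X")


def read_structure(path, fmt: Optional[str] = None) -> list:
    """Read a PDB or mmCIF file into one ChainStructure per polymer chain.

    Heteroatoms, waters and hydrogens are excluded; only the first model of a
    multi-model file is used; for alternate locations the highest-occupancy
    conformer is kept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    st.remove_alternative_conformations()
    st.remove_hydrogens()
    st.remove_ligands_and_waters()
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no model")
    model = st[0]
    chains = []
    entry = (st.name or path.stem).lower()
    for ch in model:
        residues = []
        seen = 0
        for res in ch:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            atoms = [
                AtomRecord(a.name, a.element.name or "C",
                           np.array([a.pos.x, a.pos.y, a.pos.z]),
                           is_heavy=a.element.name != "H")
                for a in res
            ]
            seen += 1
            residues.append(
                Residue(
                    seq_index=res.seqid.num if res.seqid.num >= 1 else seen,
                    aa=_one_letter(res.name),
                    atoms=atoms,
                    insertion_code=(res.seqid.icode or "").strip(),
                )
            )
        if residues:
            chains.append(ChainStructure(chain_id=ch.name, residues=residues, source_entry=entry))
    if not chains:
        raise EmptyStructureError(f"{path}: no polymer chain")
    return chains


def apply_transform(chain: ChainStructure, t: RigidTransform) -> ChainStructure:
    """Return a copy of `chain` with every atom mapped x -> R x + t."""
    out = chain.copy()
    for res in out.residues:
        for atom in res.atoms:
            atom.coords = t.apply(atom.coords)
    return out


def _chain_to_gemmi(chain: ChainStructure, chain_id: str) -> gemmi.Chain:
    gch = gemmi.Chain(chain_id)
    for res in chain.residues:
        gres = gemmi.Residue()
        gres.name = ONE_TO_THREE.get(res.aa, "UNK")
        gres.seqid = gemmi.SeqId(res.seq_index, res.insertion_code or " ")
        for atom in res.atoms:
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.coords)
            ga.occ = 1.0
            ga.b_iso = 0.0
            gres.add_atom(ga)
        gch.add_residue(gres)
    return gch


def write_chains(chains: Sequence[ChainStructure], path,
                 chain_ids: Optional[Sequence[str]] = None,
                 entry_name: Optional[str] = None) -> None:
    """Write bare chains to a PDB file (used for synthetic template entries)."""
    chains = list(chains)
    if not chains:
        raise ValueError("no chains to write")
    if chain_ids is None:
        chain_ids = [c.chain_id for c in chains]
    path = Path(path)
    st = gemmi.Structure()
    st.name = entry_name or path.stem
    gm = gemmi.Model("1")
    for chain, cid in zip(chains, chain_ids):
        gm.add_chain(_chain_to_gemmi(chain, cid))
    st.add_model(gm)
    st.setup_entities()
    path.parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(path))


def write_complex(model, path) -> None:
    """Write an assembled complex as a multi-chain PDB plus JSON sidecar.

    Chain IDs are remapped deterministically (A, B, C, ... in subunit
    insertion order) so repeated runs are diffable.  The sidecar records,
    per subunit, its provenance: template entry and chain, anchoring
    subunit, template pair, and placement transform.
    """
    subunits = list(model.subunits)
    if not subunits:
        raise ValueError("cannot write an empty model")
    if len(subunits) > len(CHAIN_IDS):
        raise ChainIDOverflowError(
            f"{len(subunits)} subunits exceed the {len(CHAIN_IDS)} available chain IDs"
        )
    path = Path(path)
    st = gemmi.Structure()
    st.name = path.stem
    gm = gemmi.Model("1")
    provenance = []
    for i, su in enumerate(subunits):
        cid = CHAIN_IDS[i]
        gm.add_chain(_chain_to_gemmi(su.chain, cid))
        elem = su.introduced_by
        provenance.append({
            "subunit_id": su.subunit_id,
            "chain_id": cid,
            "protein": su.protein,
            "source_entry": su.chain.source_entry,
            "source_chain": su.chain.chain_id,
            "anchor_subunit": su.anchor,
            "template_pair": (
                None if elem is None else
                [elem.interaction.acc_a, elem.interaction.acc_b]
            ),
            "transform": su.transform.to_json(),
        })
    st.add_model(gm)
    st.setup_entities()
    path.parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(path))
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    sidecar.write_text(json.dumps({"model": path.stem, "subunits": provenance},
                                  indent=1, sort_keys=True))
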