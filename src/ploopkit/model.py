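"""In-memory representation of a crystal structure.

The containers here are deliberately thin: a structure is a list of chains,
a chain an ordered list of residues, a residue a list of heavy atoms with
author numbering. All downstream analysis (motif annotation, Mg2+ shell
geometry, SASA) works on these objects, so that synthetic structures and
parsed PDB/mmCIF entries go through exactly the same code path.

Conventions
-----------
* Author numbering (``auth_seq_num`` + insertion code) identifies residues,
  so reported labels match the residue numbers printed in the literature
  (Thr19, Asp290, ...).
* Hydrogens are never stored; every distance in the pipeline is a
  heavy-atom distance.
* Waters are kept apart from polymer chains and normalised to ``HOH``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass
class AtomRecord:
    """One heavy atom in PDB naming convention (e.g. ``OG1``, ``PG``, ``O3B``)."""

    atom_name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.atom_name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.atom_name}: occupancy {self.occupancy} outside [0, 1]")

    def distance(self, other: "AtomRecord") -> float:
        return float(np.linalg.norm(self.coords - other.coords))


@dataclass
class Residue:
    chain_id: str
    auth_seq_num: int
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)
    insertion_code: str = ""
    is_hetero: bool = False

    @property
    def label(self) -> str:
        """Identifier in ``chain/NAME+number`` form, e.g. ``A/THR19``."""
        return f"{self.chain_id}/{self.res_name}{self.auth_seq_num}{self.insertion_code}"

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None

    def atoms_named(self, *names: str) -> list[AtomRecord]:
        wanted = set(names)
        return [a for a in self.atoms if a.atom_name in wanted]

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.auth_seq_num, self.insertion_code)


@dataclass
class StructureModel:
    """A single-model structure: polymer chains, hetero residues, waters."""

    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    hetero: list[Residue] = field(default_factory=list)
    waters: list[Residue] = field(default_factory=list)
    resolution: float | None = None

    def polymer_residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def all_residues(self) -> Iterator[Residue]:
        yield from self.polymer_residues()
        yield from self.hetero
        yield from self.waters

    def all_atoms(self) -> Iterator[tuple[Residue, AtomRecord]]:
        for res in self.all_residues():
            for atom in res.atoms:
                yield res, atom

    def atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.all_residues())

    def chain(self, chain_id: str) -> list[Residue]:
        return self.chains.get(chain_id, [])

    def residue_index(self, residue: Residue) -> int:
        """Position of a residue within its chain's ordered residue list."""
        chain = self.chain(residue.chain_id)
        for i, r in enumerate(chain):
            if r.key() == residue.key():
                return i
        raise KeyError(f"{residue.label} not in chain {residue.chain_id}")

    def preceding_residues(self, residue: Residue, n: int) -> list[Residue]:
        """The n N-terminal neighbours (i-1 ... i-n) in chain order, nearest first."""
        i = self.residue_index(residue)
        chain = self.chain(residue.chain_id)
        return [chain[j] for j in range(i - 1, i - 1 - n, -1) if j >= 0]

    def following_residue(self, residue: Residue) -> Residue | None:
        i = self.residue_index(residue)
        chain = self.chain(residue.chain_id)
        return chain[i + 1] if i + 1 < len(chain) else None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """A rigidly moved copy: x -> R x + t. Used by superposition and tests."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        out = StructureModel(id=self.id, resolution=self.resolution)
        for cid, residues in self.chains.items():
            out.chains[cid] = [_transform_residue(r, rotation, translation) for r in residues]
        out.hetero = [_transform_residue(r, rotation, translation) for r in self.hetero]
        out.waters = [_transform_residue(r, rotation, translation) for r in self.waters]
        return out


def _transform_residue(res: Residue, rot: np.ndarray, trans: np.ndarray) -> Residue:
    atoms = [
        AtomRecord(a.atom_name, a.element, rot @ a.coords + trans, a.occupancy, a.altloc, a.is_hetero)
        for a in res.atoms
    ]
    return Residue(res.chain_id, res.auth_seq_num, res.res_name, atoms, res.insertion_code, res.is_hetero)
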