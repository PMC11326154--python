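"""Coordinate models: atoms, unit cells, and conversion to/from gemmi.

Residue numbering is 1-based author numbering throughout the package;
ranges are inclusive on both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import gemmi
import numpy as np

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


@dataclass
class Atom:
    """A single atom with author residue numbering and Cartesian coordinates (A)."""

    atom_id: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    xyz: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 15.0
    is_water: bool = False

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,):
            raise ValueError("xyz must be a 3-vector")
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1 (1-based author numbering)")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def copy(self) -> "Atom":
        return replace(self, xyz=self.xyz.copy())


@dataclass
class StructureModel:
    """A crystallographic coordinate model in a single unit cell.

    Parameters
    ----------
    atoms:
        Atom records; coordinates are Cartesian angstroms.
    cell:
        (a, b, c, alpha, beta, gamma) with lengths in A and angles in degrees.
    space_group:
        Hermann-Mauguin symbol. Synthetic generation is restricted to P1.
    """

    atoms: list[Atom]
    cell: tuple[float, float, float, float, float, float]
    space_group: str = "P1"

    def __post_init__(self) -> None:
        self.cell = tuple(float(x) for x in self.cell)
        if len(self.cell) != 6:
            raise ValueError("cell must be (a, b, c, alpha, beta, gamma)")

    # -- geometry ---------------------------------------------------------

    @property
    def gemmi_cell(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(*self.cell)

    @property
    def orth_matrix(self) -> np.ndarray:
        """3x3 matrix A with r_cartesian = A @ x_fractional."""
        return np.array(self.gemmi_cell.orth.mat.tolist(), dtype=float)

    @property
    def volume(self) -> float:
        return self.gemmi_cell.volume

    def fractional_coords(self, wrap: bool = True) -> np.ndarray:
        """(n, 3) fractional coordinates, wrapped into [0, 1) if requested."""
        inv = np.linalg.inv(self.orth_matrix)
        frac = self.coords() @ inv.T
        if wrap:
            frac = frac - np.floor(frac)
        return frac

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    # -- bookkeeping ------------------------------------------------------

    def residue_indices(self) -> list[int]:
        """Sorted unique residue indices of non-water atoms."""
        return sorted({a.residue_index for a in self.atoms if not a.is_water})

    def heavy_atoms(self, include_waters: bool = False) -> list[Atom]:
        return [
            a
            for a in self.atoms
            if not a.is_hydrogen and (include_waters or not a.is_water)
        ]

    def atoms_of_residue(self, residue_index: int) -> list[Atom]:
        return [a for a in self.atoms if a.residue_index == residue_index]

    def copy(self) -> "StructureModel":
        return StructureModel(
            atoms=[a.copy() for a in self.atoms],
            cell=self.cell,
            space_group=self.space_group,
        )

    def translated(self, shift_cartesian: Sequence[float]) -> "StructureModel":
        shift = np.asarray(shift_cartesian, dtype=float)
        out = self.copy()
        for a in out.atoms:
            a.xyz = a.xyz + shift
        return out

    # -- gemmi conversion -------------------------------------------------

    def to_gemmi(self, b_override: dict[int, float] | None = None) -> gemmi.Structure:
        """Build a gemmi Structure; optionally override B-factors per residue."""
        st = gemmi.Structure()
        st.name = "allomap"
        st.cell = self.gemmi_cell
        st.spacegroup_hm = self.space_group
        model = gemmi.Model("1")
        chains: dict[str, gemmi.Chain] = {}
        current: dict[str, tuple[int, gemmi.Residue] | None] = {}
        for atom in self.atoms:
            ch = chains.get(atom.chain_id)
            if ch is None:
                ch = gemmi.Chain(atom.chain_id)
                chains[atom.chain_id] = ch
                current[atom.chain_id] = None
            cur = current[atom.chain_id]
            if cur is None or cur[0] != atom.residue_index:
                res = gemmi.Residue()
                res.name = atom.residue_name
                res.seqid = gemmi.SeqId(atom.residue_index, " ")
                ch.add_residue(res)
                res = ch[len(ch) - 1]
                current[atom.chain_id] = (atom.residue_index, res)
            else:
                res = cur[1]
            ga = gemmi.Atom()
            ga.name = atom.atom_id
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.xyz)
            ga.occ = atom.occupancy
            if b_override is not None:
                ga.b_iso = b_override.get(atom.residue_index, 0.0)
            else:
                ga.b_iso = atom.b_factor
            res.add_atom(ga)
        for ch in chains.values():
            model.add_chain(ch)
        st.add_model(model)
        st.setup_entities()
        return st

    @classmethod
    def from_gemmi(cls, st: gemmi.Structure) -> "StructureModel":
        cell = st.cell
        if cell.volume <= 0 or (cell.a == 1 and cell.b == 1 and cell.c == 1):
            raise ValueError(
                "structure has no unit cell (missing CRYST1 / _cell record)"
            )
        atoms: list[Atom] = []
        model = st[0]
        for chain in model:
            for res in chain:
                water = res.name.upper() in WATER_NAMES
                for at in res:
                    atoms.append(
                        Atom(
                            atom_id=at.name,
                            element=at.element.name,
                            residue_index=res.seqid.num,
                            residue_name=res.name,
                            chain_id=chain.name,
                            xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                            occupancy=at.occ,
                            b_factor=at.b_iso,
                            is_water=water,
                        )
                    )
        sg = st.spacegroup_hm or "P1"
        return cls(
            atoms=atoms,
            cell=(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma),
            space_group=sg,
        )
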