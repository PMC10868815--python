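"""Atomic data model: atoms, structures, roles, and basic geometry.

Coordinates are stored in Angstrom throughout; quantum-mechanical modules
convert to Bohr internally (see :data:`solvdna.units.ANGSTROM_TO_BOHR`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

from .elements import Element, get_element

#: Residue names recognised as water.
WATER_RESIDUE_NAMES = frozenset({"WAT", "HOH", "SPC", "TIP3"})
#: Residue names recognised as monatomic ions, with formal charges.
ION_RESIDUE_CHARGES = {"MG": 2, "CL": -1}


class Role(enum.Enum):
    """Role tag of an atom within a solvated-DNA system."""

    DNA = "DNA"
    WATER = "water"
    ION = "ion"
    CAP = "cap"


@dataclass
class Atom:
    """A single atom: element, position (Angstrom), role and grouping."""

    element: Element
    position: np.ndarray
    role: Role
    molecule_id: int
    atom_name: str = ""
    residue_name: str = ""
    formal_charge: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"Atom position must be a finite 3-vector, got {self.position}")

    def moved_to(self, position: np.ndarray) -> "Atom":
        return replace(self, position=np.asarray(position, dtype=float))


class Structure:
    """An ordered collection of atoms.

    Atom order is stable and defines the ordering of density-fitting
    coefficients downstream, so it must never be silently permuted.
    """

    def __init__(self, atoms: Iterable[Atom], label: str = "", provenance: dict | None = None):
        self.atoms: list[Atom] = list(atoms)
        if not self.atoms:
            raise ValueError("A Structure needs at least one atom.")
        self.label = label
        self.provenance = dict(provenance or {})

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    def __getitem__(self, i: int) -> Atom:
        return self.atoms[i]

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) coordinates in Angstrom."""
        return np.array([a.position for a in self.atoms])

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([a.element.atomic_number for a in self.atoms])

    @property
    def symbols(self) -> list[str]:
        return [a.element.symbol for a in self.atoms]

    @property
    def net_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)

    def molecule_ids(self) -> list[int]:
        """Distinct molecule ids in first-appearance order."""
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.molecule_id, None)
        return list(seen)

    def atoms_of_molecule(self, molecule_id: int) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.molecule_id == molecule_id]

    def water_molecules(self) -> list[list[int]]:
        """Atom-index groups of complete water molecules (1 O + 2 H)."""
        waters = []
        for mid in self.molecule_ids():
            idx = self.atoms_of_molecule(mid)
            if all(self.atoms[i].role is Role.WATER for i in idx):
                symbols = sorted(self.atoms[i].element.symbol for i in idx)
                if symbols == ["H", "H", "O"]:
                    waters.append(idx)
        return waters

    def subset(self, indices: Sequence[int], label: str = "") -> "Structure":
        """New Structure from a subset of atom indices (order preserved)."""
        return Structure(
            [self.atoms[i] for i in indices],
            label=label or self.label,
            provenance={**self.provenance, "subset_of": self.label, "indices": list(indices)},
        )

    def transformed(self, rotation: np.ndarray | None = None, translation: np.ndarray | None = None) -> "Structure":
        """Rigidly transform all coordinates (rotation applied first)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        return Structure(
            [a.moved_to(R @ a.position + t) for a in self.atoms],
            label=self.label,
            provenance=dict(self.provenance),
        )


def center_of_nuclear_charge(atoms: Iterable[Atom]) -> np.ndarray:
    """Nuclear-charge-weighted mean position, sum(Z_A R_A)/sum(Z_A), in Angstrom.

    This is the standard reference point for dipole moments of molecular
    partitions that are not exactly neutral.
    """
    atoms = list(atoms)
    if not atoms:
        raise ValueError("center_of_nuclear_charge needs at least one atom.")
    Z = np.array([a.element.atomic_number for a in atoms], dtype=float)
    R = np.array([a.position for a in atoms])
    return (Z[:, None] * R).sum(axis=0) / Z.sum()


def heavy_atom_count(structure: Structure) -> int:
    """Number of non-hydrogen atoms (the unit used to size training sets)."""
    return int(np.sum(structure.atomic_numbers > 1))


def assign_roles(residue_name: str, atoms: list[tuple[str, str]]) -> tuple[Role, int]:
    """Decide the role (and formal charge) of a residue.

    Parameters
    ----------
    residue_name : str
        PDB residue name.
    atoms : list of (atom_name, element_symbol)
        Contents of the residue, used for the water composition check.

    Returns
    -------
    (Role, formal_charge_per_atom)
    """
    name = residue_name.strip().upper()
    if name in WATER_RESIDUE_NAMES:
        symbols = sorted(sym for _, sym in atoms)
        if symbols != ["H", "H", "O"]:
            raise ValueError(
                f"Residue {residue_name!r} is named like water but is not one O + two H "
                f"(got {symbols}); refusing to guess its role."
            )
        return Role.WATER, 0
    if name in ION_RESIDUE_CHARGES and len(atoms) == 1:
        return Role.ION, ION_RESIDUE_CHARGES[name]
    return Role.DNA, 0
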