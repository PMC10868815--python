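"""Regular cubic scalar fields and Gaussian cube file I/O.

Fields live in atomic units: origins/spacings in Bohr, density values in
e/Bohr^3 (or Hartree/e for potentials).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structure import Structure
from .units import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM

#: Default padding (Bohr) added around a structure's bounding box.
DEFAULT_PADDING_BOHR = 5.0


@dataclass
class ScalarField:
    """Values on a regular cubic Cartesian grid (atomic units)."""

    origin: np.ndarray  # (3,) Bohr
    spacing: float      # Bohr, cubic
    values: np.ndarray  # (nx, ny, nz)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise ValueError(f"Grid spacing must be positive, got {self.spacing}")
        if self.values.ndim != 3:
            raise ValueError("ScalarField values must be a 3D array.")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def points(self) -> np.ndarray:
        """(N, 3) voxel-center coordinates in Bohr, C order of ``values``."""
        axes = [self.origin[d] + self.spacing * np.arange(self.shape[d]) for d in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=-1)

    def integrate(self) -> float:
        """integral of the field over the grid (midpoint quadrature)."""
        return float(self.values.sum() * self.voxel_volume)

    def same_grid(self, other: "ScalarField", tol: float = 1e-8) -> bool:
        return (
            self.shape == other.shape
            and abs(self.spacing - other.spacing) < tol
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def copy_with(self, values: np.ndarray) -> "ScalarField":
        return ScalarField(self.origin.copy(), self.spacing, values)


def make_grid(structure: Structure, spacing: float, padding: float = DEFAULT_PADDING_BOHR) -> ScalarField:
    """An empty field covering ``structure`` plus ``padding`` Bohr on all sides."""
    pos = structure.positions * ANGSTROM_TO_BOHR
    lo = pos.min(axis=0) - padding
    hi = pos.max(axis=0) + padding
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
    return ScalarField(lo, spacing, np.zeros(tuple(shape)))


def write_cube(field: ScalarField, structure: Structure, path: str | Path, comment: str = "") -> None:
    """Write a Gaussian cube file (Bohr units, positive voxel counts)."""
    if len(structure) == 0:
        raise ValueError("Cannot write a cube file for an empty structure.")
    nx, ny, nz = field.shape
    h = field.spacing
    with open(path, "w") as fh:
        fh.write((comment or "solvdna scalar field") + "\n")
        fh.write("density/potential on a cubic grid, atomic units\n")
        fh.write(f"{len(structure):5d} {field.origin[0]:12.6f} {field.origin[1]:12.6f} {field.origin[2]:12.6f}\n")
        fh.write(f"{nx:5d} {h:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        fh.write(f"{ny:5d} {0.0:12.6f} {h:12.6f} {0.0:12.6f}\n")
        fh.write(f"{nz:5d} {0.0:12.6f} {0.0:12.6f} {h:12.6f}\n")
        for atom in structure.atoms:
            x, y, z = atom.position * ANGSTROM_TO_BOHR
            Z = atom.element.atomic_number
            fh.write(f"{Z:5d} {float(Z):12.6f} {x:12.6f} {y:12.6f} {z:12.6f}\n")
        flat = field.values.reshape(nx * ny, nz)
        for row in flat:
            for start in range(0, nz, 6):
                fh.write("".join(f"{v:14.6e}" for v in row[start : start + 6]) + "\n")


def read_cube(path: str | Path) -> tuple[ScalarField, np.ndarray, np.ndarray]:
    """Read a Gaussian cube file.

    Returns
    -------
    (field, atomic_numbers, positions_angstrom)
    """
    lines = Path(path).read_text().splitlines()
    natom_line = lines[2].split()
    natoms = int(natom_line[0])
    origin = np.array([float(v) for v in natom_line[1:4]])
    counts, steps = [], []
    for i in range(3):
        parts = lines[3 + i].split()
        counts.append(int(parts[0]))
        steps.append([float(v) for v in parts[1:4]])
    steps = np.array(steps)
    if counts[0] < 0:
        raise ValueError(f"Cube file {path}: Angstrom-unit cube files are not supported.")
    diag = np.diag(steps)
    if not np.allclose(steps, np.diag(diag)) or not np.allclose(diag, diag[0]):
        raise ValueError(f"Cube file {path}: only axis-aligned cubic grids are supported.")
    numbers, coords = [], []
    for i in range(natoms):
        parts = lines[6 + i].split()
        numbers.append(int(parts[0]))
        coords.append([float(v) for v in parts[2:5]])
    data = np.array(" ".join(lines[6 + natoms :]).split(), dtype=float)
    nx, ny, nz = counts
    if data.size != nx * ny * nz:
        raise ValueError(f"Cube file {path}: voxel count {data.size} does not match header {nx*ny*nz}.")
    field = ScalarField(origin, float(diag[0]), data.reshape(nx, ny, nz))
    return field, np.array(numbers), np.array(coords) * BOHR_TO_ANGSTROM
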