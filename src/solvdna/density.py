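"""Density-fitting coefficients: evaluation, moments, normalisation, projection.

A :class:`DensityCoefficients` object stores one scalar per basis function
in (atom, shell, m=-l..+l) order.  Two storage conventions exist:

* raw: the coefficients C_ikm of the Gaussian expansion itself; the only
  form accepted by evaluation and moment routines;
* population-normalised: each coefficient is rescaled by its shell's
  population-sized integral factor so that l=0 entries are electron
  populations and l>0 entries are O(1).  This is the form used as network
  training targets.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from scipy.linalg import solve

from .basis import AuxBasis
from .grids import DEFAULT_PADDING_BOHR, ScalarField, make_grid
from .harmonics import rotation_matrix, solid_harmonics
from .structure import Structure
from .units import ANGSTROM_TO_BOHR

_EVAL_CHUNK = 200_000  # points per evaluation chunk, bounds peak memory


class DensityCoefficients:
    def __init__(self, structure: Structure, basis: AuxBasis, values: np.ndarray, normalized: bool = False):
        self.structure = structure
        self.basis = basis
        self.values = np.asarray(values, dtype=float)
        self.normalized = bool(normalized)
        expected = self.n_functions(structure, basis)
        if self.values.shape != (expected,):
            raise ValueError(
                f"Coefficient vector has {self.values.shape} entries, structure/basis require {expected}."
            )

    # -- layout ---------------------------------------------------------
    @staticmethod
    def n_functions(structure: Structure, basis: AuxBasis) -> int:
        return sum(basis.n_functions(a.element.symbol) for a in structure.atoms)

    def iter_blocks(self):
        """Yield (atom_index, atom, shell, slice) over the flat layout."""
        offset = 0
        for i, atom in enumerate(self.structure.atoms):
            for shell in self.basis.shells(atom.element.symbol):
                n = shell.n_components
                yield i, atom, shell, slice(offset, offset + n)
                offset += n

    def atom_slices(self) -> list[slice]:
        """Flat-coefficient slice per atom."""
        bounds = [0]
        for atom in self.structure.atoms:
            bounds.append(bounds[-1] + self.basis.n_functions(atom.element.symbol))
        return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]

    def copy(self) -> "DensityCoefficients":
        return DensityCoefficients(self.structure, self.basis, self.values.copy(), self.normalized)

    def _require_raw(self, op: str) -> None:
        if self.normalized:
            raise ValueError(
                f"{op} requires raw coefficients; call normalize_populations(..., 'to_raw') first."
            )

    # -- persistence ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write a self-describing JSON coefficient container."""
        payload = {
            "format": "solvdna-coefficients-1",
            "units": "atomic (exponents Bohr^-2); positions Angstrom",
            "harmonic_convention": "real solid harmonics, m=-l..+l, no Condon-Shortley phase",
            "normalized": self.normalized,
            "basis": self.basis.to_dict(),
            "atoms": [
                {
                    "symbol": a.element.symbol,
                    "position": list(map(float, a.position)),
                    "role": a.role.value,
                    "molecule_id": a.molecule_id,
                    "name": a.atom_name,
                    "charge": a.formal_charge,
                }
                for a in self.structure.atoms
            ],
            "values": self.values.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "DensityCoefficients":
        from .basis import _basis_from_dict
        from .elements import get_element
        from .structure import Atom, Role

        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "solvdna-coefficients-1":
            raise ValueError(f"{path} is not a solvdna coefficient container.")
        basis = _basis_from_dict(payload["basis"])
        atoms = [
            Atom(
                get_element(a["symbol"]),
                np.array(a["position"]),
                Role(a["role"]),
                a["molecule_id"],
                atom_name=a.get("name", ""),
                formal_charge=a.get("charge", 0),
            )
            for a in payload["atoms"]
        ]
        structure = Structure(atoms, label=Path(path).stem)
        return cls(structure, basis, np.array(payload["values"]), payload["normalized"])


# ---------------------------------------------------------------------------
def evaluate_density(coeffs: DensityCoefficients, points: np.ndarray) -> np.ndarray:
    """Evaluate the fitted density at Cartesian points (Bohr) -> e/Bohr^3."""
    coeffs._require_raw("evaluate_density")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.zeros(len(points))
    for start in range(0, len(points), _EVAL_CHUNK):
        chunk = points[start : start + _EVAL_CHUNK]
        out[start : start + _EVAL_CHUNK] = _evaluate_chunk(coeffs, chunk)
    return out


#: Gaussians are dropped beyond exp(-a r^2) < e^-34 (~2e-15)
_NEGLIGIBLE_EXPONENT = 34.0


def _evaluate_chunk(coeffs: DensityCoefficients, points: np.ndarray) -> np.ndarray:
    values = np.zeros(len(points))
    pos_bohr = coeffs.structure.positions * ANGSTROM_TO_BOHR
    per_atom: dict[int, list] = {}
    for i, atom, shell, sl in coeffs.iter_blocks():
        if np.any(coeffs.values[sl]):
            per_atom.setdefault(i, []).append((shell, sl))
    for i, shells in per_atom.items():
        d = points - pos_bohr[i]
        r2 = np.einsum("ij,ij->i", d, d)
        a_min = min(sh.exponent for sh, _ in shells)
        mask = r2 <= _NEGLIGIBLE_EXPONENT / a_min
        if not np.any(mask):
            continue
        dm, r2m = d[mask], r2[mask]
        harm: dict[int, np.ndarray] = {}
        acc = np.zeros(int(mask.sum()))
        for shell, sl in shells:
            if shell.l not in harm:
                harm[shell.l] = solid_harmonics(shell.l, dm)
            acc += (harm[shell.l] @ coeffs.values[sl]) * (shell.norm * np.exp(-shell.exponent * r2m))
        values[mask] += acc
    return values


def evaluate_on_grid(coeffs: DensityCoefficients, grid: ScalarField) -> ScalarField:
    """Evaluate the fitted density on every voxel of ``grid``.

    Exploits the grid structure: each atom only touches the sub-box of
    voxels within its widest Gaussian's support radius.
    """
    out = np.zeros(grid.shape)
    pos_bohr = coeffs.structure.positions * ANGSTROM_TO_BOHR
    h = grid.spacing
    axes = [grid.origin[d] + h * np.arange(grid.shape[d]) for d in range(3)]
    per_atom: dict[int, list] = {}
    for i, atom, shell, sl in coeffs.iter_blocks():
        if np.any(coeffs.values[sl]):
            per_atom.setdefault(i, []).append((shell, sl))
    for i, shells in per_atom.items():
        a_min = min(sh.exponent for sh, _ in shells)
        r_max = np.sqrt(_NEGLIGIBLE_EXPONENT / a_min)
        lo = np.maximum(np.ceil((pos_bohr[i] - r_max - grid.origin) / h).astype(int), 0)
        hi = np.minimum(np.floor((pos_bohr[i] + r_max - grid.origin) / h).astype(int) + 1, grid.shape)
        if np.any(lo >= hi):
            continue
        dx = axes[0][lo[0] : hi[0]] - pos_bohr[i][0]
        dy = axes[1][lo[1] : hi[1]] - pos_bohr[i][1]
        dz = axes[2][lo[2] : hi[2]] - pos_bohr[i][2]
        r2 = dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        mask = r2 <= r_max**2
        if not np.any(mask):
            continue
        gx, gy, gz = np.meshgrid(dx, dy, dz, indexing="ij")
        dm = np.stack([gx[mask], gy[mask], gz[mask]], axis=-1)
        r2m = r2[mask]
        harm: dict[int, np.ndarray] = {}
        acc = np.zeros(int(mask.sum()))
        for shell, sl in shells:
            if shell.l not in harm:
                harm[shell.l] = solid_harmonics(shell.l, dm)
            acc += (harm[shell.l] @ coeffs.values[sl]) * (shell.norm * np.exp(-shell.exponent * r2m))
        sub = out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        sub[mask] += acc
    return grid.copy_with(out)


def density_field(coeffs: DensityCoefficients, spacing: float, padding: float = DEFAULT_PADDING_BOHR) -> ScalarField:
    """Convenience: evaluate on a default grid around the structure."""
    grid = make_grid(coeffs.structure, spacing, padding)
    return evaluate_on_grid(coeffs, grid)


# ---------------------------------------------------------------------------
def analytic_moments(coeffs: DensityCoefficients, ref_point: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Closed-form total electron count and electronic first moment.

    Returns
    -------
    (total_electrons, electronic_dipole)
        ``electronic_dipole`` = integral rho(r) (r - ref) dV in atomic units
        (note: this is the moment of the electron density, not yet the
        molecular dipole, which subtracts it from the nuclear term).
        ``ref_point`` is given in Angstrom; default is the origin.
    """
    ref = np.zeros(3) if ref_point is None else np.asarray(ref_point, float) * ANGSTROM_TO_BOHR
    total = 0.0
    moment = np.zeros(3)
    pos_bohr = coeffs.structure.positions * ANGSTROM_TO_BOHR
    for i, atom, shell, sl in coeffs.iter_blocks():
        c = coeffs.values[sl]
        if coeffs.normalized:
            c = c / shell.normalization_scale
        if shell.l == 0:
            q = float(c[0]) * shell.population_factor
            total += q
            moment += q * (pos_bohr[i] - ref)
        elif shell.l == 1:
            # components ordered (y, z, x)
            t = shell.first_moment_factor
            moment += t * np.array([c[2], c[0], c[1]])
    return total, moment


def total_electrons(coeffs: DensityCoefficients) -> float:
    return analytic_moments(coeffs)[0]


# ---------------------------------------------------------------------------
def normalize_populations(coeffs: DensityCoefficients, direction: str) -> DensityCoefficients:
    """Convert between raw coefficients and population-normalised targets.

    ``to_normalized`` multiplies every coefficient by its shell's
    normalisation scale (so l=0 entries become electron populations);
    ``to_raw`` inverts exactly.
    """
    if direction not in ("to_normalized", "to_raw"):
        raise ValueError(f"direction must be 'to_normalized' or 'to_raw', got {direction!r}")
    if direction == "to_normalized" and coeffs.normalized:
        raise ValueError("Coefficients are already population-normalised.")
    if direction == "to_raw" and not coeffs.normalized:
        raise ValueError("Coefficients are already raw.")
    out = coeffs.values.copy()
    for _, _, shell, sl in coeffs.iter_blocks():
        s = shell.normalization_scale
        out[sl] = out[sl] * s if direction == "to_normalized" else out[sl] / s
    return DensityCoefficients(coeffs.structure, coeffs.basis, out, normalized=(direction == "to_normalized"))


# ---------------------------------------------------------------------------
def project_to_basis(
    reference: ScalarField,
    structure: Structure,
    basis: AuxBasis,
    regularization: float = 0.0,
) -> tuple[DensityCoefficients, float]:
    """Least-squares fit of the auxiliary expansion to a gridded density.

    Minimises sum over voxels of (rho_fit - rho_ref)^2 * voxel_volume.

    Returns
    -------
    (coefficients, rms_residual)
        ``rms_residual`` in e/Bohr^3 over the grid.
    """
    nfun = DensityCoefficients.n_functions(structure, basis)
    points = reference.points()
    y = reference.values.ravel()
    G = np.zeros((nfun, nfun))
    b = np.zeros(nfun)
    template = DensityCoefficients(structure, basis, np.zeros(nfun))
    pos_bohr = structure.positions * ANGSTROM_TO_BOHR
    for start in range(0, len(points), _EVAL_CHUNK):
        chunk = points[start : start + _EVAL_CHUNK]
        A = _design_matrix(template, chunk, pos_bohr)
        G += A.T @ A
        b += A.T @ y[start : start + _EVAL_CHUNK]
    lam = regularization
    cond = np.linalg.cond(G)
    if cond > 1e12 and lam == 0.0:
        lam = 1e-10 * np.trace(G) / nfun
        warnings.warn(
            f"Projection normal equations are ill-conditioned (cond={cond:.2e}); "
            f"solving with Tikhonov regularization lambda={lam:.2e}.",
            RuntimeWarning,
        )
    c = solve(G + lam * np.eye(nfun), b, assume_a="pos")
    coeffs = DensityCoefficients(structure, basis, c)
    fit = evaluate_density(coeffs, points)
    rms = float(np.sqrt(np.mean((fit - y) ** 2)))
    return coeffs, rms


def _design_matrix(template: DensityCoefficients, points: np.ndarray, pos_bohr: np.ndarray) -> np.ndarray:
    A = np.zeros((len(points), len(template.values)))
    cache: dict[int, dict] = {}
    for i, atom, shell, sl in template.iter_blocks():
        cc = cache.setdefault(i, {})
        if "d" not in cc:
            d = points - pos_bohr[i]
            cc["d"] = d
            cc["r2"] = np.einsum("ij,ij->i", d, d)
        if shell.l not in cc:
            cc[shell.l] = solid_harmonics(shell.l, cc["d"])
        radial = shell.norm * np.exp(-shell.exponent * cc["r2"])
        A[:, sl] = cc[shell.l] * radial[:, None]
    return A


# ---------------------------------------------------------------------------
def rotate_coefficients(coeffs: DensityCoefficients, R: np.ndarray, translation_angstrom: np.ndarray | None = None) -> DensityCoefficients:
    """Rigidly transform structure and coefficients together.

    l>0 blocks are rotated with the degree-l real-harmonic rotation
    matrices, so the represented density co-moves with the structure.
    """
    new_structure = coeffs.structure.transformed(R, translation_angstrom)
    out = coeffs.values.copy()
    mats = {l: rotation_matrix(l, R) for l in (1, 2)}
    for _, _, shell, sl in coeffs.iter_blocks():
        if shell.l > 0:
            out[sl] = mats[shell.l] @ out[sl]
    return DensityCoefficients(new_structure, coeffs.basis, out, coeffs.normalized)
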