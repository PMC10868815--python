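"""Physics analyses of fitted electron densities.

Implements the solvation-physics toolbox: radial water-shell assignment,
per-molecule dipole moments from partitioned densities, electrostatic
potentials on isodensity surfaces (with mean-aligned RMSD comparison),
solvation density-difference maps, and helix-axis potential profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .density import DensityCoefficients, analytic_moments, evaluate_density
from .grids import ScalarField, make_grid
from .structure import Atom, Role, Structure, center_of_nuclear_charge
from .units import ANGSTROM_TO_BOHR, AU_TO_DEBYE, BOHR_TO_ANGSTROM

#: radial water-shell boundaries in Angstrom (CPPTRAJ defaults):
#: shell 1 is 0 < r <= 3.4, shell 2 is 3.4 < r <= 5.0, shell 3 is r > 5.0.
SHELL_BOUNDS = (3.4, 5.0)


@dataclass
class ShellAssignment:
    """Per-water shell index (1, 2 or 3) and radial distance in Angstrom."""

    shells: dict[int, int]   # molecule_id -> shell index
    radii: dict[int, float]  # molecule_id -> r


@dataclass
class SurfaceSample:
    """Points of an isodensity surface with (optionally) potentials on them."""

    points: np.ndarray            # (N, 3) Bohr
    isovalue: float               # e/Bohr^3
    r_bar: float                  # Angstrom, mean distance to nearest DNA atom
    values: np.ndarray | None = None  # potentials, a.u.


@dataclass
class AxisProfile:
    """Axis-binned potential statistics, one bin per base-pair P-P midpoint."""

    bin_centers: np.ndarray  # (nbins, 3) Angstrom
    means: np.ndarray
    stds: np.ndarray
    counts: np.ndarray


# ---------------------------------------------------------------------------
def assign_water_shells(structure: Structure, center: str = "ion") -> ShellAssignment:
    """Classify waters into radial shells around an ion or the cluster center.

    ``center='ion'`` requires exactly one ion; ``center='cluster_cnc'``
    uses the center of nuclear charge of all atoms (the ion-free cluster
    convention).  Boundaries are inclusive on the upper edge.
    """
    waters = structure.water_molecules()
    if not waters:
        raise ValueError("Shell assignment needs at least one water molecule.")
    if center == "ion":
        ions = [i for i, a in enumerate(structure.atoms) if a.role is Role.ION]
        if len(ions) != 1:
            raise ValueError(f"center='ion' requires exactly one ion, found {len(ions)}.")
        ref = structure.atoms[ions[0]].position
    elif center == "cluster_cnc":
        ref = center_of_nuclear_charge(structure.atoms)
    else:
        raise ValueError(f"Unknown center {center!r}; use 'ion' or 'cluster_cnc'.")
    shells, radii = {}, {}
    for group in waters:
        o_idx = next(i for i in group if structure.atoms[i].element.symbol == "O")
        r = float(np.linalg.norm(structure.atoms[o_idx].position - ref))
        mid = structure.atoms[o_idx].molecule_id
        if r <= SHELL_BOUNDS[0]:
            shells[mid] = 1
        elif r <= SHELL_BOUNDS[1]:
            shells[mid] = 2
        else:
            shells[mid] = 3
        radii[mid] = r
    return ShellAssignment(shells, radii)


# ---------------------------------------------------------------------------
def partition_to_molecule(coeffs: DensityCoefficients, molecule_id: int) -> DensityCoefficients:
    """Zero all coefficients not centered on the molecule's atoms."""
    values = coeffs.values.copy()
    slices = coeffs.atom_slices()
    for i, atom in enumerate(coeffs.structure.atoms):
        if atom.molecule_id != molecule_id:
            values[slices[i]] = 0.0
    return DensityCoefficients(coeffs.structure, coeffs.basis, values, coeffs.normalized)


def molecular_dipole(
    coeffs: DensityCoefficients,
    molecule_id: int,
    method: str = "analytic",
    spacing: float = 0.1,
    padding: float = 6.0,
) -> tuple[np.ndarray, float]:
    """Dipole moment of one molecule from its partitioned density.

    The density is partitioned by keeping only the basis functions
    centered on the molecule's atoms.  Because such partitions need not be
    exactly neutral, the dipole is referenced to the molecule's center of
    nuclear charge:

        mu = sum_A Z_A (R_A - R_ref) - integral rho_part(r) (r - R_ref) dV.

    ``method='grid'`` integrates the partitioned density on a cubic grid
    (default 0.1 Bohr, molecule bounding box + 6 Bohr); ``'analytic'``
    uses closed-form Gaussian moments.

    Returns
    -------
    (dipole_vector_au, magnitude_debye)
    """
    coeffs._require_raw("molecular_dipole")
    structure = coeffs.structure
    mol_atoms = [structure.atoms[i] for i in structure.atoms_of_molecule(molecule_id)]
    if not mol_atoms:
        raise ValueError(f"Molecule id {molecule_id} not present in the structure.")
    part = partition_to_molecule(coeffs, molecule_id)
    ref = center_of_nuclear_charge(mol_atoms)
    nuclear = np.zeros(3)
    for a in mol_atoms:
        nuclear += a.element.atomic_number * (a.position - ref) * ANGSTROM_TO_BOHR
    if method == "analytic":
        _, electronic = analytic_moments(part, ref_point=ref)
    elif method == "grid":
        mol = Structure(mol_atoms, label="partition")
        grid = make_grid(mol, spacing, padding)
        pts = grid.points()
        rho = evaluate_density(part, pts)
        ref_bohr = ref * ANGSTROM_TO_BOHR
        electronic = (rho[:, None] * (pts - ref_bohr)).sum(axis=0) * grid.voxel_volume
    else:
        raise ValueError(f"Unknown dipole method {method!r}; use 'analytic' or 'grid'.")
    mu = nuclear - electronic
    return mu, float(np.linalg.norm(mu) * AU_TO_DEBYE)


def shell_dipole_summary(
    assignment: ShellAssignment, dipoles: dict[int, float]
) -> dict[int, tuple[float, float, int]]:
    """Mean/std/count of dipole magnitudes (Debye) per water shell."""
    missing = set(assignment.shells) - set(dipoles)
    if missing:
        raise ValueError(f"No dipole supplied for water molecules {sorted(missing)}.")
    out: dict[int, tuple[float, float, int]] = {}
    for shell in (1, 2, 3):
        vals = [dipoles[m] for m, s in assignment.shells.items() if s == shell]
        if vals:
            out[shell] = (float(np.mean(vals)), float(np.std(vals)), len(vals))
        else:
            out[shell] = (float("nan"), float("nan"), 0)
    return out


# ---------------------------------------------------------------------------
def isodensity_surface(
    density: ScalarField, isovalue: float, dna_atoms: list[Atom]
) -> SurfaceSample:
    """Vertices of the density isosurface and their mean DNA distance r-bar.

    Surface points are marching-cubes vertices (trilinear interpolation
    along grid edges crossing the isovalue).  ``r_bar`` is the mean over
    points of the distance to the nearest atom in ``dna_atoms``, in
    Angstrom.
    """
    from skimage.measure import marching_cubes

    vmin, vmax = float(density.values.min()), float(density.values.max())
    if not (vmin < isovalue < vmax):
        raise ValueError(
            f"Isovalue {isovalue} outside the field's value range [{vmin:.3e}, {vmax:.3e}]."
        )
    verts, _, _, _ = marching_cubes(density.values, level=isovalue, spacing=(density.spacing,) * 3)
    points = verts + density.origin
    if not dna_atoms:
        raise ValueError("isodensity_surface needs at least one reference atom.")
    apos = np.array([a.position for a in dna_atoms]) * ANGSTROM_TO_BOHR
    dmin = np.min(np.linalg.norm(points[:, None, :] - apos[None, :, :], axis=-1), axis=1)
    r_bar = float(dmin.mean() * BOHR_TO_ANGSTROM)
    return SurfaceSample(points=points, isovalue=isovalue, r_bar=r_bar)


# ---------------------------------------------------------------------------
# electrostatic potential of the fitted density
# ---------------------------------------------------------------------------
def _f0(d: np.ndarray, a: float) -> np.ndarray:
    """erf(sqrt(a) d)/d with its smooth d->0 limit."""
    s = math.sqrt(a)
    small = s * d < 1e-5
    out = np.empty_like(d)
    out[~small] = erf(s * d[~small]) / d[~small]
    ds = d[small]
    out[small] = 2 * s / math.sqrt(math.pi) * (1 - (s * ds) ** 2 / 3 + (s * ds) ** 4 / 10)
    return out


def _f1_over_d(d: np.ndarray, a: float) -> np.ndarray:
    """f'(d)/d for f = erf(sqrt(a) d)/d, smooth at the origin."""
    s = math.sqrt(a)
    A = 2 * s / math.sqrt(math.pi)
    small = s * d < 1e-4
    out = np.empty_like(d)
    dn = d[~small]
    out[~small] = (A * np.exp(-a * dn**2) / dn - erf(s * dn) / dn**2) / dn
    ds = d[small]
    out[small] = A * (-2 * a / 3 + a**2 * ds**2 * 0.4)
    return out


def _f2_term(d: np.ndarray, a: float) -> np.ndarray:
    """(f'' - f'/d)/d^2, the radial factor of second-derivative terms."""
    s = math.sqrt(a)
    A = 2 * s / math.sqrt(math.pi)
    small = s * d < 1e-3
    out = np.empty_like(d)
    dn = d[~small]
    e = np.exp(-a * dn**2)
    out[~small] = (-2 * A * a * e - 3 * A * e / dn**2 + 3 * erf(s * dn) / dn**3) / dn**2
    out[small] = 0.8 * A * a**2  # leading term of the Taylor series
    return out


def esp_at_points(
    coeffs: DensityCoefficients, points: np.ndarray, include_nuclei: bool = True
) -> np.ndarray:
    """Electrostatic potential V(r) of nuclei plus fitted density, in a.u.

    V(r) = sum_A Z_A/|r - R_A| - integral rho(r')/|r - r'| dV'.

    The Gaussian Coulomb integrals are closed-form: an s function of
    charge q contributes q erf(sqrt(a) d)/d; l=1 and l=2 functions follow
    from solid-harmonic derivatives of that kernel.  Points must not
    coincide with a nucleus when nuclei are included.
    """
    coeffs._require_raw("esp_at_points")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    structure = coeffs.structure
    pos_bohr = structure.positions * ANGSTROM_TO_BOHR
    V = np.zeros(len(points))
    if include_nuclei:
        for i, atom in enumerate(structure.atoms):
            d = np.linalg.norm(points - pos_bohr[i], axis=1)
            if np.any(d < 1e-8):
                raise ValueError(
                    f"Evaluation point coincides with nucleus {atom.atom_name} (atom {i})."
                )
            V += atom.element.atomic_number / d

    for i, atom, shell, sl in coeffs.iter_blocks():
        c = coeffs.values[sl]
        if not np.any(c):
            continue
        disp = points - pos_bohr[i]
        d = np.linalg.norm(disp, axis=1)
        a = shell.exponent
        pref = shell.norm * (math.pi / a) ** 1.5
        if shell.l == 0:
            V -= c[0] * pref * _f0(d, a)
        elif shell.l == 1:
            # S_1m(grad) f = f'/d * (y, z, x); prefactor (-1/2a) from the
            # solid-harmonic derivative identity
            g = _f1_over_d(d, a)
            comp = np.stack([disp[:, 1], disp[:, 2], disp[:, 0]], axis=-1)
            V -= pref * (-1.0 / (2 * a)) * (comp @ c) * g
        elif shell.l == 2:
            # S_2m(grad) f = (f'' - f'/d)/d^2 * S_2m(r)
            from .harmonics import solid_harmonics

            g = _f2_term(d, a)
            S = solid_harmonics(2, disp)
            V -= pref * (1.0 / (2 * a)) ** 2 * (S @ c) * g
        else:
            raise NotImplementedError(f"Closed-form ESP implemented for l <= 2, got l={shell.l}.")
    return V


def esp_at_points_quadrature(
    coeffs: DensityCoefficients,
    points: np.ndarray,
    spacing: float = 0.1,
    padding: float = 8.0,
    include_nuclei: bool = True,
) -> np.ndarray:
    """Grid-quadrature reference for :func:`esp_at_points` (validation only)."""
    coeffs._require_raw("esp_at_points_quadrature")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    structure = coeffs.structure
    grid = make_grid(structure, spacing, padding)
    gpts = grid.points()
    rho = evaluate_density(coeffs, gpts)
    w = rho * grid.voxel_volume
    V = np.zeros(len(points))
    pos_bohr = structure.positions * ANGSTROM_TO_BOHR
    for k, p in enumerate(points):
        d = np.linalg.norm(gpts - p, axis=1)
        d = np.maximum(d, 0.5 * spacing)  # soften the self-voxel singularity
        V[k] = -np.sum(w / d)
        if include_nuclei:
            dn = np.linalg.norm(pos_bohr - p, axis=1)
            V[k] += np.sum(structure.atomic_numbers / dn)
    return V


def esp_rmsd(v_test: np.ndarray, v_ref: np.ndarray) -> float:
    """RMSD of two potential series after aligning their averages.

    Subtracting each series' mean removes the arbitrary constant offset
    before comparison, so adding any constant to either input leaves the
    result unchanged.
    """
    v_test = np.asarray(v_test, float)
    v_ref = np.asarray(v_ref, float)
    if v_test.shape != v_ref.shape:
        raise ValueError(f"Potential series differ in length: {v_test.shape} vs {v_ref.shape}.")
    diff = (v_test - v_test.mean()) - (v_ref - v_ref.mean())
    return float(np.sqrt(np.mean(diff**2)))


# ---------------------------------------------------------------------------
def zero_water_coefficients(coeffs: DensityCoefficients) -> DensityCoefficients:
    """Zero out all basis functions centered on water atoms."""
    values = coeffs.values.copy()
    slices = coeffs.atom_slices()
    for i, atom in enumerate(coeffs.structure.atoms):
        if atom.role is Role.WATER:
            values[slices[i]] = 0.0
    return DensityCoefficients(coeffs.structure, coeffs.basis, values, coeffs.normalized)


def density_difference(
    coeffs_solvated: DensityCoefficients,
    coeffs_gas: DensityCoefficients,
    grid: ScalarField,
) -> ScalarField:
    """Solvation density difference rho_DNA,polarized - rho_DNA,gas.

    Water-centered basis functions of the solvated prediction are zeroed
    (leaving the "polarized" DNA density); both densities are then
    evaluated on ``grid`` and subtracted.  The DNA atom lists of the two
    coefficient sets must agree in order, element and position.
    """
    dna_solv = [a for a in coeffs_solvated.structure.atoms if a.role is not Role.WATER]
    dna_gas = [a for a in coeffs_gas.structure.atoms if a.role is not Role.WATER]
    if len(dna_solv) != len(dna_gas) or any(
        a.element.symbol != b.element.symbol or not np.allclose(a.position, b.position, atol=1e-6)
        for a, b in zip(dna_solv, dna_gas)
    ):
        raise ValueError("Solvated and gas-phase structures disagree on their DNA atoms.")
    polarized = zero_water_coefficients(coeffs_solvated)
    rho_pol = evaluate_density(polarized, grid.points()).reshape(grid.shape)
    rho_gas = evaluate_density(coeffs_gas, grid.points()).reshape(grid.shape)
    return grid.copy_with(rho_pol - rho_gas)


# ---------------------------------------------------------------------------
def axis_profile(surface: SurfaceSample, p_pairs: list[tuple[Atom, Atom]]) -> AxisProfile:
    """Bin surface potentials by nearest base-pair P-P midpoint.

    The global mean of the potential values is shifted to zero first; each
    surface point is then assigned to the nearest midpoint of a
    cross-strand phosphorus pair, and per-bin means and standard
    deviations are returned in the given base-sequence order.
    """
    if surface.values is None:
        raise ValueError("Surface has no potential values; evaluate them first.")
    if not p_pairs:
        raise ValueError("axis_profile needs at least one P-atom pair.")
    centers = np.array([(a.position + b.position) / 2.0 for a, b in p_pairs])
    pts_ang = surface.points * BOHR_TO_ANGSTROM
    d = np.linalg.norm(pts_ang[:, None, :] - centers[None, :, :], axis=-1)
    bin_of = np.argmin(d, axis=1)
    vals = surface.values - surface.values.mean()
    means = np.zeros(len(centers))
    stds = np.zeros(len(centers))
    counts = np.zeros(len(centers), dtype=int)
    for k in range(len(centers)):
        mask = bin_of == k
        counts[k] = mask.sum()
        if counts[k]:
            means[k] = vals[mask].mean()
            stds[k] = vals[mask].std()
        else:
            means[k] = np.nan
            stds[k] = np.nan
    return AxisProfile(centers, means, stds, counts)
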