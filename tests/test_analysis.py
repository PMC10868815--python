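"""Solvation analyses: shells, dipoles, ESP, difference maps, axis profiles."""

import math

import numpy as np
import pytest
from scipy.special import erf

from solvdna.analysis import (
    SurfaceSample,
    assign_water_shells,
    axis_profile,
    density_difference,
    esp_at_points,
    esp_at_points_quadrature,
    esp_rmsd,
    isodensity_surface,
    molecular_dipole,
    shell_dipole_summary,
    zero_water_coefficients,
)
from solvdna.basis import default_basis
from solvdna.density import DensityCoefficients, density_field
from solvdna.elements import get_element
from solvdna.structure import Atom, Role, Structure
from solvdna.synth import (
    MockOracleParams,
    make_solvated_system,
    mock_dft_coefficients,
    water_coords,
)
from solvdna.units import ANGSTROM_TO_BOHR


def water_at(distance, mol_id, direction=(1.0, 0.0, 0.0)):
    d = np.asarray(direction) / np.linalg.norm(direction)
    shift = distance * d
    return [
        Atom(get_element(n[0]), p + shift, Role.WATER, mol_id, n, "WAT")
        for n, p in zip(("O", "H1", "H2"), water_coords())
    ]


class TestShellAssignment:
    def _ion_with_waters_at(self, radii):
        atoms = [Atom(get_element("Mg"), np.zeros(3), Role.ION, 0, "MG", "MG", 2)]
        for k, r in enumerate(radii, start=1):
            theta = 0.7 * k
            atoms += water_at(r, k, (math.cos(theta), math.sin(theta), 0.1 * k))
        return Structure(atoms)

    def _ion_with_water_on_axis(self, r):
        # exact axis-aligned placement so the boundary radius is exact
        atoms = [Atom(get_element("Mg"), np.zeros(3), Role.ION, 0, "MG", "MG", 2)]
        atoms += water_at(r, 1, (1.0, 0.0, 0.0))
        return Structure(atoms)

    def test_boundary_340_is_shell_one(self):
        s = self._ion_with_water_on_axis(3.4)
        assert assign_water_shells(s, "ion").shells[1] == 1

    def test_just_past_boundary_is_shell_two(self):
        s = self._ion_with_water_on_axis(3.41)
        assert assign_water_shells(s, "ion").shells[1] == 2

    def test_boundary_500_is_shell_two(self):
        s = self._ion_with_water_on_axis(5.0)
        assert assign_water_shells(s, "ion").shells[1] == 2

    def test_radial_ladder_counts(self):
        radii = np.arange(1.0, 11.0)  # 1..10 A
        s = self._ion_with_waters_at(radii)
        asg = assign_water_shells(s, "ion")
        counts = {k: sum(1 for v in asg.shells.values() if v == k) for k in (1, 2, 3)}
        assert counts == {1: 3, 2: 2, 3: 5}  # 1,2,3 | 4,5 | 6..10

    def test_cluster_center_uses_nuclear_charge(self):
        atoms = water_at(0.0, 0) + water_at(6.0, 1)
        s = Structure(atoms)
        asg = assign_water_shells(s, "cluster_cnc")
        assert set(asg.shells.values()) <= {1, 2, 3}
        assert len(asg.shells) == 2

    def test_ion_center_requires_exactly_one_ion(self, toy_water):
        with pytest.raises(ValueError, match="exactly one ion"):
            assign_water_shells(toy_water, "ion")


class TestMolecularDipole:
    def test_monomer_calibrated_to_gas_phase_value(self, water_monomer_coeffs):
        _, mag = molecular_dipole(water_monomer_coeffs, 0, "analytic")
        assert mag == pytest.approx(1.85, abs=0.02)

    def test_grid_matches_analytic_within_001_debye(self, basis, oracle_params):
        s = make_solvated_system("water_cluster", 2, seed=9)
        coeffs = mock_dft_coefficients(s, oracle_params, basis)
        for mid in (0, 1):
            _, mag_a = molecular_dipole(coeffs, mid, "analytic")
            _, mag_g = molecular_dipole(coeffs, mid, "grid", spacing=0.1)
            assert abs(mag_a - mag_g) < 0.01

    def test_spherical_partition_has_zero_dipole(self, basis):
        s = Structure([Atom(get_element("O"), [1.0, 2.0, 3.0], Role.DNA, 0, "O")])
        sh = basis.shells("O")[0]
        values = np.zeros(DensityCoefficients.n_functions(s, basis))
        values[0] = 8.0 / sh.population_factor
        coeffs = DensityCoefficients(s, basis, values)
        _, mag = molecular_dipole(coeffs, 0, "analytic")
        assert mag == pytest.approx(0.0, abs=1e-10)


class TestShellSummary:
    def test_empty_shells_have_zero_count(self):
        from solvdna.analysis import ShellAssignment

        asg = ShellAssignment({0: 1, 1: 1}, {0: 2.0, 1: 3.0})
        summary = shell_dipole_summary(asg, {0: 2.0, 1: 3.0})
        assert summary[1] == (pytest.approx(2.5), pytest.approx(0.5), 2)
        assert summary[2][2] == 0 and math.isnan(summary[2][0])

    def test_missing_dipole_is_an_error(self):
        from solvdna.analysis import ShellAssignment

        asg = ShellAssignment({0: 1, 1: 2}, {0: 2.0, 1: 4.0})
        with pytest.raises(ValueError):
            shell_dipole_summary(asg, {0: 2.0})


class TestIsodensitySurface:
    def test_spherical_gaussian_gives_analytic_radius(self, basis):
        s = Structure([Atom(get_element("H"), np.zeros(3), Role.DNA, 0, "H")])
        sh = basis.shells("H")[0]
        values = np.zeros(DensityCoefficients.n_functions(s, basis))
        c = 1.0
        values[0] = c
        coeffs = DensityCoefficients(s, basis, values)
        field = density_field(coeffs, 0.15, padding=6.0)
        iso = 0.01
        surf = isodensity_surface(field, iso, list(s.atoms))
        r_analytic = math.sqrt(-math.log(iso / (c * sh.norm)) / sh.exponent)
        radii = np.linalg.norm(surf.points, axis=1)
        assert abs(radii.mean() - r_analytic) < 0.15  # within one voxel
        assert radii.std() < 0.05

    def test_higher_isovalue_smaller_rbar(self, water_monomer, water_monomer_coeffs):
        field = density_field(water_monomer_coeffs, 0.2)
        lo = isodensity_surface(field, 0.001, list(water_monomer.atoms))
        hi = isodensity_surface(field, 0.01, list(water_monomer.atoms))
        assert hi.r_bar < lo.r_bar
        assert len(lo.points) > 0 and len(hi.points) > 0

    def test_isovalue_outside_range_is_an_error(self, water_monomer, water_monomer_coeffs):
        field = density_field(water_monomer_coeffs, 0.3)
        with pytest.raises(ValueError, match="outside"):
            isodensity_surface(field, 1e6, list(water_monomer.atoms))


class TestESP:
    def test_single_s_gaussian_closed_form(self, basis):
        s = Structure([Atom(get_element("H"), np.zeros(3), Role.DNA, 0, "H")])
        sh = basis.shells("H")[0]
        q = 0.8
        values = np.zeros(DensityCoefficients.n_functions(s, basis))
        values[0] = q / sh.population_factor
        coeffs = DensityCoefficients(s, basis, values)
        for d in (0.5, 2.0, 6.0):
            v = esp_at_points(coeffs, [[d, 0.0, 0.0]], include_nuclei=False)
            assert v[0] == pytest.approx(-q * erf(math.sqrt(sh.exponent) * d) / d, rel=1e-10)
        # d -> 0 limit: -q * 2 sqrt(a/pi)
        v0 = esp_at_points(coeffs, [[1e-7, 0.0, 0.0]], include_nuclei=False)
        assert v0[0] == pytest.approx(-q * 2 * math.sqrt(sh.exponent / math.pi), rel=1e-6)

    def test_closed_form_matches_quadrature_on_mock_water(self, water_monomer, water_monomer_coeffs):
        rng = np.random.default_rng(4)
        center = water_monomer.positions.mean(axis=0) * ANGSTROM_TO_BOHR
        pts = center + rng.normal(size=(5, 3)) * 1.0 + np.array([6.0, 0, 0])
        v_closed = esp_at_points(water_monomer_coeffs, pts)
        v_quad = esp_at_points_quadrature(water_monomer_coeffs, pts, spacing=0.1)
        assert np.abs(v_closed - v_quad).max() < 1e-3

    def test_neutral_molecule_far_field_decays_faster_than_monopole(self, water_monomer_coeffs):
        v10 = esp_at_points(water_monomer_coeffs, [[10.0, 0.0, 0.0]])[0]
        v20 = esp_at_points(water_monomer_coeffs, [[20.0, 0.0, 0.0]])[0]
        # a monopole would only halve; a neutral molecule falls at least ~4x
        assert abs(v20) < abs(v10) / 3.5

    def test_point_on_nucleus_is_an_error(self, water_monomer, water_monomer_coeffs):
        p = water_monomer.positions[0] * ANGSTROM_TO_BOHR
        with pytest.raises(ValueError, match="nucleus"):
            esp_at_points(water_monomer_coeffs, [p])


class TestEspRmsd:
    def test_constant_offset_gives_zero(self):
        v = np.array([0.1, -0.3, 0.5, 0.2])
        assert esp_rmsd(v + 7.5, v) == pytest.approx(0.0, abs=1e-12)

    def test_identical_series_zero(self):
        v = np.array([1.0, 2.0, 3.0])
        assert esp_rmsd(v, v) == 0.0

    def test_three_point_toy_by_hand(self):
        # test = (1, 2, 6), ref = 0: after centering, diff = (-2, -1, 3)
        assert esp_rmsd(np.array([1.0, 2.0, 6.0]), np.zeros(3)) == pytest.approx(
            math.sqrt(14.0 / 3.0)
        )

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            esp_rmsd(np.zeros(3), np.zeros(4))


class TestDensityDifference:
    @pytest.fixture()
    def solvated_and_gas(self, basis, oracle_params):
        solv = make_solvated_system("solvated_fragment", 6, seed=13)
        gas_idx = [i for i, a in enumerate(solv.atoms) if a.role is not Role.WATER]
        gas = solv.subset(gas_idx, label="gas")
        c_solv = mock_dft_coefficients(solv, oracle_params, basis)
        c_gas = mock_dft_coefficients(gas, oracle_params, basis)
        return solv, gas, c_solv, c_gas

    def test_identical_dna_coefficients_give_zero_field(self, basis, oracle_params):
        gas = make_solvated_system("solvated_fragment", 0, seed=13)
        c1 = mock_dft_coefficients(gas, oracle_params, basis)
        from solvdna.grids import make_grid

        grid = make_grid(gas, 0.4)
        diff = density_difference(c1, c1, grid)
        assert np.abs(diff.values).max() == pytest.approx(0.0, abs=1e-14)

    def test_water_coefficients_are_zeroed(self, solvated_and_gas, basis, oracle_params):
        solv, gas, c_solv, c_gas = solvated_and_gas
        zeroed = zero_water_coefficients(c_solv)
        slices = zeroed.atom_slices()
        for i, atom in enumerate(solv.atoms):
            if atom.role is Role.WATER:
                assert np.all(zeroed.values[slices[i]] == 0)
            else:
                assert np.allclose(zeroed.values[slices[i]], c_solv.values[slices[i]])

    def test_polarization_signal_concentrates_near_solvent(self, solvated_and_gas):
        from solvdna.grids import make_grid

        solv, gas, c_solv, c_gas = solvated_and_gas
        grid = make_grid(gas, 0.3)
        diff = density_difference(c_solv, c_gas, grid)
        assert np.abs(diff.values).sum() * diff.voxel_volume > 1e-4

    def test_antisymmetric_after_water_zeroing(self, solvated_and_gas):
        from solvdna.grids import make_grid

        solv, gas, c_solv, c_gas = solvated_and_gas
        zeroed = zero_water_coefficients(c_solv)
        grid = make_grid(gas, 0.4)
        forward = density_difference(zeroed, c_gas, grid)
        backward = density_difference(c_gas, zeroed, grid)
        assert np.allclose(forward.values, -backward.values, atol=1e-12)

    def test_dna_mismatch_is_an_error(self, solvated_and_gas, basis, oracle_params):
        solv, gas, c_solv, _ = solvated_and_gas
        other = make_solvated_system("water_cluster", 2, seed=1)
        c_other = mock_dft_coefficients(other, oracle_params, basis)
        from solvdna.grids import make_grid

        with pytest.raises(ValueError, match="disagree"):
            density_difference(c_solv, c_other, make_grid(gas, 0.5))


class TestAxisProfile:
    def _surface(self, points, values):
        return SurfaceSample(
            points=np.asarray(points, float) * ANGSTROM_TO_BOHR,
            isovalue=0.001,
            r_bar=1.0,
            values=np.asarray(values, float),
        )

    def _p_pair(self, z):
        a = Atom(get_element("P"), [3.0, 0.0, z], Role.DNA, 0, "P")
        b = Atom(get_element("P"), [-3.0, 0.0, z], Role.DNA, 1, "P")
        return (a, b)

    def test_single_bin_mean_is_zero_after_shift(self):
        surf = self._surface([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [5.0, 6.0, 7.0])
        prof = axis_profile(surf, [self._p_pair(0.0)])
        assert prof.means[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_symmetric_bins(self):
        pts = [[0, 0, 0.1], [0, 0, -0.1], [0, 0, 9.9], [0, 0, 10.1]]
        vals = [1.0, 1.0, -1.0, -1.0]
        surf = self._surface(pts, vals)
        prof = axis_profile(surf, [self._p_pair(0.0), self._p_pair(10.0)])
        assert prof.means == pytest.approx([1.0, -1.0])

    def test_every_point_in_exactly_one_bin(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(40, 3)) * 4
        surf = self._surface(pts, rng.normal(size=40))
        prof = axis_profile(surf, [self._p_pair(z) for z in (-3.0, 0.0, 3.0)])
        assert prof.counts.sum() == 40

    def test_values_required(self):
        surf = SurfaceSample(np.zeros((2, 3)), 0.001, 1.0, values=None)
        with pytest.raises(ValueError):
            axis_profile(surf, [self._p_pair(0.0)])
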