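"""Synthetic test-system generators and the mock-DFT density oracle.

This module produces every input the rest of the package is exercised on:

* idealized B-form DNA of arbitrary sequence (planar Watson-Crick base
  pairs on a 36 deg / 3.38 Angstrom helix, simplified sugar-phosphate
  backbone with correct covalent topology),
* water clusters and ion solvation shells packed by rejection sampling,
* a mock-DFT oracle that assigns density-fitting coefficients with exact,
  analytically known properties: promolecule s populations per atom, an
  intrinsic water dipole calibrated to the gas-phase monomer value
  (1.85 D), and a one-shot induced-dipole polarization response to the
  local electric field of ions and neighbouring water dipoles.

The oracle is a physics-flavoured stand-in for an ab initio reference
generator, not a DFT emulator: its purpose is ground truth with
controllable structure, so that training, metrics and analysis can be
validated against closed-form expectations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .basis import AuxBasis
from .density import DensityCoefficients, normalize_populations
from .elements import get_element
from .structure import Atom, Role, Structure, center_of_nuclear_charge
from .units import ANGSTROM_TO_BOHR, AU_TO_DEBYE

# -- water geometry (gas-phase experimental) --------------------------------
WATER_OH = 0.9572          # Angstrom
WATER_HOH = 104.52         # degrees
WATER_MONOMER_DIPOLE_D = 1.85  # Debye, the monomeric-water calibration point

# -- helix parameters --------------------------------------------------------
RISE = 3.38                # Angstrom per base-pair step
TWIST = 36.0               # degrees per base-pair step

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
_PURINES = ("A", "G")


def water_coords() -> np.ndarray:
    """O, H1, H2 of a gas-phase water; O at origin, dipole axis along +x."""
    half = math.radians(WATER_HOH / 2.0)
    h1 = np.array([WATER_OH * math.cos(half), WATER_OH * math.sin(half), 0.0])
    h2 = np.array([WATER_OH * math.cos(half), -WATER_OH * math.sin(half), 0.0])
    return np.array([[0.0, 0.0, 0.0], h1, h2])


def _rz(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    from .harmonics import random_rotation

    return random_rotation(rng)


# ===========================================================================
# Nucleobase templates
# ===========================================================================
def _hexagon(side: float = 1.37) -> np.ndarray:
    """Vertices of a regular hexagon, circumradius = side, CCW from +90 deg."""
    ang = np.radians(90 + 60 * np.arange(6))
    return side * np.stack([np.cos(ang), np.sin(ang)], axis=-1)


@lru_cache(maxsize=None)
def _base_template(letter: str) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    """Planar nucleobase template.

    Returns (atom_names, element_symbols, coords) with the glycosidic
    nitrogen (N9 for purines, N1 for pyrimidines) at the origin and the
    base plane z=0.  Geometry is idealized: aromatic rings are regular
    polygons (side 1.37 A) with standard exocyclic bond lengths.
    """
    names: list[str] = []
    symbols: list[str] = []
    coords: list[np.ndarray] = []

    def add(name: str, sym: str, xy, z: float = 0.0) -> None:
        names.append(name)
        symbols.append(sym)
        coords.append(np.array([xy[0], xy[1], z]))

    hexagon = _hexagon()
    ring6 = dict(zip(["N1", "C2", "N3", "C4", "C5", "C6"], hexagon))
    center6 = np.zeros(2)

    def radial(p: np.ndarray, length: float, frm: np.ndarray) -> np.ndarray:
        d = p - frm
        return p + length * d / np.linalg.norm(d)

    if letter in _PURINES:
        # fuse a regular pentagon on the C4-C5 edge, outside the hexagon
        c4, c5 = ring6["C4"], ring6["C5"]
        mid = 0.5 * (c4 + c5)
        out_dir = (mid - center6) / np.linalg.norm(mid - center6)
        apothem5 = 1.37 / (2 * math.tan(math.radians(36)))
        center5 = mid + apothem5 * out_dir
        r5 = 1.37 / (2 * math.sin(math.radians(36)))
        a4 = math.atan2(*(c4 - center5)[::-1])
        a5 = math.atan2(*(c5 - center5)[::-1])
        # choose the rotation direction that walks outside the hexagon
        delta = (a5 - a4) % (2 * math.pi)
        step = -2 * math.pi / 5 if delta < math.pi else 2 * math.pi / 5
        ring5 = {"C4": c4, "C5": c5}
        for k, name in enumerate(["N9", "C8", "N7"], start=1):
            ang = a4 + step * k
            ring5[name] = center5 + r5 * np.array([math.cos(ang), math.sin(ang)])
        for name in ["N1", "C2", "N3", "C4", "C5", "C6"]:
            add(name, name[0], ring6[name])
        for name in ["N7", "C8", "N9"]:
            add(name, name[0], ring5[name])
        add("H8", "H", radial(ring5["C8"], 1.08, center5))
        if letter == "A":
            n6 = radial(ring6["C6"], 1.34, center6)
            add("N6", "N", n6)
            _add_amino_h(add, "H61", "H62", n6, ring6["C6"], center6)
            add("H2", "H", radial(ring6["C2"], 1.08, center6))
        else:  # G
            add("O6", "O", radial(ring6["C6"], 1.23, center6))
            add("H1", "H", radial(ring6["N1"], 1.01, center6))
            n2 = radial(ring6["C2"], 1.34, center6)
            add("N2", "N", n2)
            _add_amino_h(add, "H21", "H22", n2, ring6["C2"], center6)
        origin = ring5["N9"]
    else:
        for name in ["N1", "C2", "N3", "C4", "C5", "C6"]:
            add(name, name[0], ring6[name])
        add("O2", "O", radial(ring6["C2"], 1.23, center6))
        add("H6", "H", radial(ring6["C6"], 1.08, center6))
        if letter == "C":
            n4 = radial(ring6["C4"], 1.34, center6)
            add("N4", "N", n4)
            _add_amino_h(add, "H41", "H42", n4, ring6["C4"], center6)
            add("H5", "H", radial(ring6["C5"], 1.08, center6))
        elif letter == "T":
            add("H3", "H", radial(ring6["N3"], 1.01, center6))
            add("O4", "O", radial(ring6["C4"], 1.23, center6))
            c7 = radial(ring6["C5"], 1.50, center6)
            add("C7", "C", c7)
            u = (c7 - ring6["C5"]) / np.linalg.norm(c7 - ring6["C5"])
            perp = np.array([-u[1], u[0]])
            add("H71", "H", c7 + 1.09 * (math.cos(math.radians(70.5)) * u + math.sin(math.radians(70.5)) * perp))
            for sgn in (1.0, -1.0):
                xy = c7 + 1.09 * (math.cos(math.radians(70.5)) * u - 0.5 * math.sin(math.radians(70.5)) * perp)
                add("H72" if sgn > 0 else "H73", "H", xy, z=sgn * 1.09 * math.sin(math.radians(70.5)) * math.sqrt(0.75))
        else:
            raise ValueError(f"Invalid base letter {letter!r}; expected one of A, C, G, T.")
        origin = ring6["N1"]

    xyz = np.array(coords)
    xyz[:, :2] -= origin
    return tuple(names), tuple(symbols), xyz


def _add_amino_h(add, name1: str, name2: str, n_pos: np.ndarray, c_pos: np.ndarray, center: np.ndarray) -> None:
    """Two in-plane amino hydrogens at +-60 deg off the C->N direction."""
    u = (n_pos - c_pos) / np.linalg.norm(n_pos - c_pos)
    for name, sign in ((name1, 1.0), (name2, -1.0)):
        a = math.radians(60.0) * sign
        d = np.array([u[0] * math.cos(a) - u[1] * math.sin(a), u[0] * math.sin(a) + u[1] * math.cos(a)])
        add(name, "H", n_pos + 1.01 * d)


# ===========================================================================
# Watson-Crick pair frame
# ===========================================================================
#: C1'-C1' separation across a pair and the glycosidic-bond geometry.
_C1_HALF_SEP = 5.2
_LAMBDA = math.radians(54.5)
_GLYCOSIDIC = 1.47
_WC_NN = 2.9  # purine N1 to pyrimidine N3 hydrogen-bond distance


def _slot_anchors() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    c1p_1 = np.array([-_C1_HALF_SEP, 0.0, 0.0])
    c1p_2 = np.array([+_C1_HALF_SEP, 0.0, 0.0])
    g1 = c1p_1 + _GLYCOSIDIC * np.array([math.cos(_LAMBDA), math.sin(_LAMBDA), 0.0])
    g2 = c1p_2 + _GLYCOSIDIC * np.array([-math.cos(_LAMBDA), math.sin(_LAMBDA), 0.0])
    return c1p_1, c1p_2, g1, g2


#: second Watson-Crick hydrogen bond anchoring the pair orientation:
#: purine C6 substituent to pyrimidine C4 substituent.
_WC_SECOND = {"A": ("N6", "O4"), "G": ("O6", "N4")}


@lru_cache(maxsize=None)
def _pair_template(purine_letter: str) -> dict:
    """Watson-Crick pair with the purine in slot 1 (x<0), plane z=0.

    The in-plane orientation of each base is solved from two hydrogen-bond
    constraints that define the pairing pattern: purine N1 to pyrimidine
    N3, and the C6/C4 substituent pair (A N6...T O4, G O6...C N4), both at
    2.9 Angstrom.  Among the solution branches the one with the largest
    covalent-bond safety margin between the two bases is kept, so that
    geometric bond detection never links the paired bases.
    """
    from scipy.optimize import fsolve

    pyr_letter = _COMPLEMENT[purine_letter]
    _, _, g1, g2 = _slot_anchors()
    pur_names, pur_syms, pur_xyz = _base_template(purine_letter)
    pyr_names, pyr_syms, pyr_xyz = _base_template(pyr_letter)
    name6, name4 = _WC_SECOND[purine_letter]

    pur_radii = np.array([get_element(s).covalent_radius for s in pur_syms])
    pyr_radii = np.array([get_element(s).covalent_radius for s in pyr_syms])
    cutoffs = 1.2 * (pur_radii[:, None] + pyr_radii[None, :])

    best = None
    for mir1 in (False, True):
        for mir2 in (False, True):
            P = pur_xyz * np.array([1.0, -1.0, -1.0]) if mir1 else pur_xyz
            Y = pyr_xyz * np.array([1.0, -1.0, -1.0]) if mir2 else pyr_xyz
            q_n1 = P[pur_names.index("N1")][:2]
            q_x6 = P[pur_names.index(name6)][:2]
            r_n3 = Y[pyr_names.index("N3")][:2]
            r_x4 = Y[pyr_names.index(name4)][:2]

            def equations(t):
                R1 = _rz(t[0])[:2, :2]
                R2 = _rz(t[1])[:2, :2]
                return [
                    np.linalg.norm((g1[:2] + R1 @ q_n1) - (g2[:2] + R2 @ r_n3)) - _WC_NN,
                    np.linalg.norm((g1[:2] + R1 @ q_x6) - (g2[:2] + R2 @ r_x4)) - _WC_NN,
                ]

            for t10 in np.linspace(-math.pi, math.pi, 7):
                for t20 in np.linspace(-math.pi, math.pi, 7):
                    sol, _, ier, _ = fsolve(equations, [t10, t20], full_output=True)
                    if ier != 1 or max(abs(v) for v in equations(sol)) > 1e-8:
                        continue
                    pur = P @ _rz(sol[0]).T + g1
                    pyr = Y @ _rz(sol[1]).T + g2
                    n1 = pur[pur_names.index("N1")]
                    n3 = pyr[pyr_names.index("N3")]
                    # orientation gates: major-groove substituents above the
                    # hydrogen-bond line, bases between the strands
                    if pur[pur_names.index("C6")][1] <= n1[1]:
                        continue
                    if pyr[pyr_names.index("C4")][1] <= n3[1]:
                        continue
                    if n1[0] >= n3[0] or abs(n1[1] - n3[1]) > 1.5:
                        continue
                    dists = np.linalg.norm(pur[:, None, :] - pyr[None, :, :], axis=-1)
                    margin = float(np.min(dists - cutoffs))
                    if best is None or margin > best["margin"]:
                        best = {"margin": margin, "pur": pur, "pyr": pyr}
    if best is None or best["margin"] < 0.2:
        raise RuntimeError(f"Watson-Crick pair construction failed for {purine_letter}.")
    return {
        "purine": (pur_names, pur_syms, best["pur"]),
        "pyrimidine": (pyr_names, pyr_syms, best["pyr"]),
    }


# ===========================================================================
# Sugar-phosphate backbone
# ===========================================================================
@lru_cache(maxsize=None)
def _sugar_template() -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    """Simplified deoxyribose template in the local attachment frame.

    Frame: origin at C1'; +x is the C1'->glycosidic-N direction; +y is the
    strand 5'->3' direction; +z completes the right-handed frame.  Two
    helix-referenced directions expressed in this frame shape the
    template: ``out`` (radially away from the helix axis) and ``phi``
    (azimuthal, toward the 3' neighbour).  The ring is a flat regular
    pentagon in the (out, strand) plane; O3' reaches azimuthally toward
    the next residue and C5'/O5' back toward the previous one so that the
    bridging phosphate lands clear of both sugars.  The direction weights
    were fixed once by requiring that geometric bond detection on
    assembled duplexes reproduces exactly the intended covalent topology
    (all valences correct, no spurious contacts).
    """
    out = np.array([-0.581, 0.0, -0.814])
    phi = np.array([-0.814, 0.0, +0.581])
    yhat = np.array([0.0, 1.0, 0.0])

    def unit(v):
        return v / np.linalg.norm(v)

    side = 1.48
    r5 = side / (2 * math.sin(math.radians(36)))
    phi0 = math.radians(-20.0)
    center = r5 * (math.cos(phi0) * out + math.sin(phi0) * yhat)
    th0 = math.atan2(-math.sin(phi0), -math.cos(phi0))
    verts = np.array(
        [
            center + r5 * (math.cos(th0 + 2 * math.pi * k / 5) * out + math.sin(th0 + 2 * math.pi * k / 5) * yhat)
            for k in range(5)
        ]
    )
    # ring walk C1'-C2'-C3'-C4'-O4'; C2' goes on the 3' (+y) side
    order = [0, 1, 2, 3, 4] if verts[1] @ yhat > verts[4] @ yhat else [0, 4, 3, 2, 1]
    names = ["C1'", "C2'", "C3'", "C4'", "O4'"]
    symbols = ["C", "C", "C", "C", "O"]
    coords = verts[order]
    xyz = dict(zip(names, coords))
    o3 = xyz["C3'"] + 1.42 * unit(unit(xyz["C3'"] - center) + 0.5 * yhat + 1.2 * phi)
    c5 = xyz["C4'"] + 1.52 * unit(unit(xyz["C4'"] - center) - 0.6 * yhat - 0.8 * phi)
    o5 = c5 + 1.42 * unit(0.6 * out - 0.5 * yhat - 0.8 * phi)
    names += ["O3'", "C5'", "O5'"]
    symbols += ["O", "C", "O"]
    coords = np.vstack([coords, o3, c5, o5])
    return tuple(names), tuple(symbols), coords


def _complete_tetrahedral(center: np.ndarray, neighbors: list[np.ndarray], n_h: int, bond: float = 1.09) -> list[np.ndarray]:
    """Positions of n_h hydrogens completing an approximately tetrahedral center."""
    units = [ (n - center) / np.linalg.norm(n - center) for n in neighbors ]
    if len(units) == 3 and n_h == 1:
        d = -sum(units)
        return [center + bond * d / np.linalg.norm(d)]
    if len(units) == 2 and n_h == 2:
        b = -(units[0] + units[1])
        b = b / np.linalg.norm(b)
        n = np.cross(units[0], units[1])
        n = n / np.linalg.norm(n)
        half = math.radians(109.5 / 2)
        return [center + bond * (math.cos(half) * b + s * math.sin(half) * n) for s in (1.0, -1.0)]
    if len(units) == 2 and n_h == 1:
        d = -(units[0] + units[1])
        return [center + bond * d / np.linalg.norm(d)]
    if len(units) == 1 and n_h == 1:
        return [center - bond * units[0]]
    raise ValueError(f"Unsupported tetrahedral completion: {len(units)} neighbours, {n_h} hydrogens.")


_SUGAR_H = {  # carbon -> (hydrogen names, heavy neighbours)
    "C1'": (("H1'",), ("C2'", "O4'")),   # third neighbour is the base N, handled separately
    "C2'": (("H2'", "H2''"), ("C1'", "C3'")),
    "C3'": (("H3'",), ("C2'", "C4'", "O3'")),
    "C4'": (("H4'",), ("C3'", "O4'", "C5'")),
    "C5'": (("H5'", "H5''"), ("C4'", "O5'")),
}


# ===========================================================================
# B-DNA builder
# ===========================================================================
def make_bdna(
    sequence: str,
    n_waters: int = 0,
    seed: int = 0,
    mg_bound: bool = False,
    label: str = "",
) -> Structure:
    """Idealized B-form duplex DNA for an arbitrary reference-strand sequence.

    Strand 1 carries ``sequence`` 5'->3'; strand 2 is its reverse
    complement.  Every nucleotide carries a 5'-phosphate; consecutive
    nucleotides are covalently linked through O3'(i)-P(i+1).  Optional
    waters are packed around the duplex and an optional Mg2+ can be bound
    to a phosphate oxygen (Mg-O distance 1.9 Angstrom).
    """
    sequence = sequence.upper()
    if not sequence or any(b not in _COMPLEMENT for b in sequence):
        raise ValueError(f"Invalid base sequence {sequence!r}: letters must be A, C, G or T.")
    c1p_1, c1p_2, g1, g2 = _slot_anchors()
    e1_slot1 = (g1 - c1p_1) / np.linalg.norm(g1 - c1p_1)
    e1_slot2 = (g2 - c1p_2) / np.linalg.norm(g2 - c1p_2)

    nucleotides: list[dict] = []   # per-nucleotide dicts of name -> position
    flip_y = np.diag([-1.0, 1.0, -1.0])  # 180 deg about y: swaps slots

    for j, letter in enumerate(sequence):
        purine_first = letter in _PURINES
        tpl = _pair_template(letter if purine_first else _COMPLEMENT[letter])
        names_a, syms_a, xyz_a = tpl["purine"] if purine_first else tpl["pyrimidine"]
        names_b, syms_b, xyz_b = tpl["pyrimidine"] if purine_first else tpl["purine"]
        if purine_first:
            xyz_1, xyz_2 = xyz_a, xyz_b
            names_1, syms_1 = names_a, syms_a
            names_2, syms_2 = names_b, syms_b
        else:
            # rotate the template pair 180 deg about y so the pyrimidine
            # occupies slot 1 (x<0); a proper rotation preserves chirality
            xyz_1, xyz_2 = xyz_a @ flip_y.T, xyz_b @ flip_y.T
            names_1, syms_1 = names_a, syms_a
            names_2, syms_2 = names_b, syms_b

        step = _rz(math.radians(TWIST * j))
        shift = np.array([0.0, 0.0, RISE * j])
        for strand, (names, syms, xyz, c1p, e1) in enumerate(
            [
                (names_1, syms_1, xyz_1, c1p_1, e1_slot1),
                (names_2, syms_2, xyz_2, c1p_2, e1_slot2),
            ],
            start=1,
        ):
            base_letter = letter if strand == 1 else _COMPLEMENT[letter]
            e2 = np.array([0.0, 0.0, 1.0 if strand == 1 else -1.0])
            e3 = np.cross(e1, e2)
            frame = np.stack([e1, e2, e3], axis=1)  # columns
            s_names, s_syms, s_xyz = _sugar_template()
            sugar = {n: c1p + frame @ p for n, p in zip(s_names, s_xyz)}
            entry = {
                "letter": base_letter,
                "strand": strand,
                "index": j,
                "base": {n: step @ xyz[i] + shift for i, n in enumerate(names)},
                "base_symbols": dict(zip(names, syms)),
                "sugar": {n: step @ p + shift for n, p in sugar.items()},
                "sugar_symbols": dict(zip(s_names, s_syms)),
            }
            nucleotides.append(entry)

    # order nucleotides strand 1 (5'->3'), then strand 2 (5'->3')
    strand1 = [n for n in nucleotides if n["strand"] == 1]
    strand2 = sorted((n for n in nucleotides if n["strand"] == 2), key=lambda n: -n["index"])

    atoms: list[Atom] = []
    mol_id = 0
    phosphate_oxygens: list[int] = []  # atom indices of OP/O5'/O3' oxygens
    for chain in (strand1, strand2):
        prev_o3: np.ndarray | None = None
        for k, nt in enumerate(chain):
            res_name = "D" + nt["letter"]
            positions: dict[str, np.ndarray] = {}
            # phosphate bridging prev O3' and this O5'
            o5 = nt["sugar"]["O5'"]
            helix_axis_point = np.array([0.0, 0.0, o5[2]])
            outward = o5 - helix_axis_point
            outward = outward / np.linalg.norm(outward)
            if prev_o3 is None:
                p_pos = o5 + 1.59 * outward
                extra = ["OP3"]
                anchor_dirs = [(o5 - p_pos) / np.linalg.norm(o5 - p_pos)]
            else:
                d = np.linalg.norm(o5 - prev_o3)
                if d > 2 * 1.59:
                    raise RuntimeError(
                        f"Backbone junction too long ({d:.2f} A) between residues; template error."
                    )
                midpoint = 0.5 * (o5 + prev_o3)
                axis = (o5 - prev_o3) / d
                h = math.sqrt(1.59**2 - (d / 2) ** 2)
                n = outward - (outward @ axis) * axis
                n = n / np.linalg.norm(n)
                p_pos = midpoint + h * n
                extra = []
                anchor_dirs = [
                    (o5 - p_pos) / np.linalg.norm(o5 - p_pos),
                    (prev_o3 - p_pos) / np.linalg.norm(prev_o3 - p_pos),
                ]
            positions["P"] = p_pos
            # terminal/charged oxygens around P
            if len(anchor_dirs) == 1:
                a = anchor_dirs[0]
                ref = np.array([0.0, 0.0, 1.0])
                if abs(a @ ref) > 0.9:
                    ref = np.array([1.0, 0.0, 0.0])
                t1 = np.cross(a, ref)
                t1 /= np.linalg.norm(t1)
                t2 = np.cross(a, t1)
                for name, ang in zip(("OP1", "OP2") + tuple(extra), (0.0, 2 * math.pi / 3, 4 * math.pi / 3)):
                    d = -a * math.cos(math.radians(70.5)) + math.sin(math.radians(70.5)) * (
                        math.cos(ang) * t1 + math.sin(ang) * t2
                    )
                    positions[name] = p_pos + 1.48 * d
            else:
                a, b = anchor_dirs
                bis = -(a + b)
                bis /= np.linalg.norm(bis)
                perp = np.cross(a, b)
                perp /= np.linalg.norm(perp)
                half = math.radians(109.5 / 2)
                positions["OP1"] = p_pos + 1.48 * (math.cos(half) * bis + math.sin(half) * perp)
                positions["OP2"] = p_pos + 1.48 * (math.cos(half) * bis - math.sin(half) * perp)

            positions.update(nt["sugar"])
            positions.update(nt["base"])
            # sugar hydrogens
            n_gly = "N9" if nt["letter"] in _PURINES else "N1"
            for carbon, (h_names, heavy) in _SUGAR_H.items():
                neighbors = [positions[h] for h in heavy]
                if carbon == "C1'":
                    neighbors.append(positions[n_gly])
                for h_name, h_pos in zip(h_names, _complete_tetrahedral(positions[carbon], neighbors, len(h_names))):
                    positions[h_name] = h_pos
            if k == len(chain) - 1:
                # 3'-terminal hydroxyl hydrogen
                positions["HO3'"] = positions["O3'"] + 0.96 * _unit(positions["O3'"] - positions["C3'"])

            symbols = {**nt["sugar_symbols"], **nt["base_symbols"]}
            for name, pos in positions.items():
                sym = symbols.get(name) or ("P" if name == "P" else name[0].upper() if name[0] in "OCNH" else name[0])
                if name.startswith(("OP", "O3", "O5")):
                    sym = "O"
                if name.startswith("H"):
                    sym = "H"
                atoms.append(
                    Atom(get_element(sym), pos, Role.DNA, mol_id, atom_name=name, residue_name=res_name)
                )
                if sym == "O" and (name.startswith("OP") or name in ("O3'", "O5'")):
                    phosphate_oxygens.append(len(atoms) - 1)
            prev_o3 = positions["O3'"]
            mol_id += 1

    structure = Structure(atoms, label=label or f"bdna-{sequence}", provenance={"sequence": sequence})

    if mg_bound:
        rng = np.random.default_rng(seed ^ 0x5F5F)
        op_idx = next(i for i in phosphate_oxygens if structure.atoms[i].atom_name == "OP1")
        op = structure.atoms[op_idx]
        p_idx = next(
            i for i, a in enumerate(structure.atoms)
            if a.atom_name == "P" and a.molecule_id == op.molecule_id
        )
        direction = _unit(op.position - structure.atoms[p_idx].position)
        mg_pos = op.position + 1.9 * direction
        atoms = list(structure.atoms) + [
            Atom(get_element("Mg"), mg_pos, Role.ION, mol_id, atom_name="MG", residue_name="MG", formal_charge=2)
        ]
        mol_id += 1
        structure = Structure(atoms, label=structure.label, provenance=structure.provenance)

    if n_waters > 0:
        structure = _add_waters(structure, n_waters, seed, start_mol_id=mol_id)
    return structure


def make_bdna_step(sequence: str, n_waters: int = 0, seed: int = 0, mg_bound: bool = False) -> Structure:
    """A solvated base-pair step (exactly two base pairs)."""
    if len(sequence) != 2:
        raise ValueError(f"A base-pair step sequence has exactly 2 letters, got {sequence!r}.")
    return make_bdna(sequence, n_waters=n_waters, seed=seed, mg_bound=mg_bound)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


# ===========================================================================
# Solvent packing
# ===========================================================================
_MIN_OO = 2.5    # Angstrom, minimum water O-O separation
_CLEARANCE = 2.2  # Angstrom, minimum water-O to solute-atom separation


def _add_waters(solute: Structure, n_waters: int, seed: int, start_mol_id: int | None = None) -> Structure:
    rng = np.random.default_rng(seed)
    solute_pos = solute.positions
    center = solute_pos.mean(axis=0)
    r_solute = np.linalg.norm(solute_pos - center, axis=1).max()
    per_water_vol = 29.9  # bulk water volume per molecule, A^3
    r_env = ((3.0 * n_waters * per_water_vol * 2.5) / (4 * math.pi)) ** (1 / 3) + r_solute + 2.0
    template = water_coords()
    oxygens: list[np.ndarray] = []
    new_atoms = list(solute.atoms)
    mol_id = start_mol_id if start_mol_id is not None else (max(solute.molecule_ids()) + 1)
    attempts = 0
    max_attempts = 5000 * max(n_waters, 1)
    while len(oxygens) < n_waters:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"Water packing failed after {max_attempts} attempts "
                f"({len(oxygens)}/{n_waters} placed); enlarge the envelope."
            )
        o = center + r_env * (rng.random(3) * 2 - 1)
        if np.linalg.norm(o - center) > r_env:
            continue
        if np.min(np.linalg.norm(solute_pos - o, axis=1)) < _CLEARANCE:
            continue
        if oxygens and np.min(np.linalg.norm(np.array(oxygens) - o, axis=1)) < _MIN_OO:
            continue
        R = _random_rotation(rng)
        coords = template @ R.T + o
        for name, pos in zip(("O", "H1", "H2"), coords):
            new_atoms.append(
                Atom(get_element(name[0]), pos, Role.WATER, mol_id, atom_name=name, residue_name="WAT")
            )
        oxygens.append(o)
        mol_id += 1
    return Structure(new_atoms, label=solute.label, provenance={**solute.provenance, "n_waters": n_waters, "seed": seed})


def make_solvated_system(kind: str, n_waters: int, seed: int = 0) -> Structure:
    """Water clusters, solvated ions, or a solvated nucleobase.

    ``kind`` is one of ``water_cluster``, ``mg_shell``, ``cl_shell``,
    ``solvated_fragment`` (an adenine base with waters).
    """
    if kind == "water_cluster":
        if n_waters < 1:
            raise ValueError("A water cluster needs at least one water molecule.")
        rng = np.random.default_rng(seed)
        # seed molecule at the origin, then pack the rest around it
        template = water_coords() @ _random_rotation(rng).T
        atoms = [
            Atom(get_element(n[0]), p, Role.WATER, 0, atom_name=n, residue_name="WAT")
            for n, p in zip(("O", "H1", "H2"), template)
        ]
        seedstruct = Structure(atoms, label=f"water-cluster-{n_waters}")
        if n_waters == 1:
            return seedstruct
        return _add_waters(seedstruct, n_waters - 1, seed + 1, start_mol_id=1)
    if kind in ("mg_shell", "cl_shell"):
        symbol, charge = ("Mg", 2) if kind == "mg_shell" else ("Cl", -1)
        ion = Atom(get_element(symbol), np.zeros(3), Role.ION, 0, atom_name=symbol.upper(),
                   residue_name=symbol.upper(), formal_charge=charge)
        solute = Structure([ion], label=f"{kind}-{n_waters}")
        return _add_waters(solute, n_waters, seed, start_mol_id=1) if n_waters else solute
    if kind == "solvated_fragment":
        base = _capped_base("A")
        return _add_waters(base, n_waters, seed) if n_waters else base
    raise ValueError(f"Unknown system kind {kind!r}.")


def _capped_base(letter: str) -> Structure:
    """A free nucleobase with the glycosidic nitrogen capped by H."""
    names, syms, xyz = _base_template(letter)
    n_gly = "N9" if letter in _PURINES else "N1"
    atoms = [
        Atom(get_element(s), p, Role.DNA, 0, atom_name=n, residue_name="D" + letter)
        for n, s, p in zip(names, syms, xyz)
    ]
    i_n = names.index(n_gly)
    ring_center = xyz[[i for i, n in enumerate(names) if n in ("N1", "C2", "N3", "C4", "C5", "C6")]].mean(axis=0)
    cap_dir = _unit(xyz[i_n] - ring_center) if letter not in _PURINES else _unit(
        xyz[i_n] - xyz[[names.index("C8"), names.index("C4")]].mean(axis=0)
    )
    atoms.append(
        Atom(get_element("H"), xyz[i_n] + 1.01 * cap_dir, Role.CAP, 0, atom_name="HCAP", residue_name="D" + letter)
    )
    return Structure(atoms, label=f"base-{letter}")


# ===========================================================================
# Mock-DFT oracle
# ===========================================================================
@dataclass
class MockOracleParams:
    """Parameters of the mock density oracle.

    water_dipole_debye : intrinsic gas-phase water dipole (calibration 1.85 D)
    water_polarizability : isotropic polarizability applied at water O, a.u.
        (experimental water value is about 9.8 Bohr^3)
    solute_polarizability : polarizability applied at non-water heavy atoms
    seed : reserved for stochastic oracle variants (the default oracle is
        deterministic)
    """

    water_dipole_debye: float = WATER_MONOMER_DIPOLE_D
    water_polarizability: float = 9.8
    solute_polarizability: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.water_polarizability < 0 or self.solute_polarizability < 0:
            raise ValueError("Polarizabilities must be non-negative.")


def _s_populations(z_eff: float, exponents: np.ndarray) -> np.ndarray:
    """Distribute z_eff electrons over s shells with weights ~ sqrt(alpha)."""
    w = np.sqrt(exponents)
    return z_eff * w / w.sum()


def mock_dft_coefficients(structure: Structure, params: MockOracleParams, basis: AuxBasis) -> DensityCoefficients:
    """Ground-truth raw coefficients for a structure.

    Promolecule s populations conserve electrons exactly (sum Z minus the
    net ionic charge).  Water molecules carry an intrinsic O-centered
    dipole along the HOH bisector; water O and solute heavy atoms receive
    a one-shot induced dipole mu = alpha * E_local, where E_local is the
    field of the ions (point charges) and of the other waters' intrinsic
    dipoles.
    """
    nfun = DensityCoefficients.n_functions(structure, basis)
    values = np.zeros(nfun)
    coeffs = DensityCoefficients(structure, basis, values)
    pos_bohr = structure.positions * ANGSTROM_TO_BOHR

    waters = structure.water_molecules()
    water_oxygen = {}
    bisectors = {}
    for idx_group in waters:
        o_idx = next(i for i in idx_group if structure.atoms[i].element.symbol == "O")
        h_idx = [i for i in idx_group if structure.atoms[i].element.symbol == "H"]
        b = _unit(
            0.5 * (pos_bohr[h_idx[0]] + pos_bohr[h_idx[1]]) - pos_bohr[o_idx]
        )
        water_oxygen[structure.atoms[o_idx].molecule_id] = o_idx
        bisectors[o_idx] = b

    mu_int = params.water_dipole_debye / AU_TO_DEBYE

    def field_at(r: np.ndarray, exclude_molecule: int) -> np.ndarray:
        E = np.zeros(3)
        for i, atom in enumerate(structure.atoms):
            if atom.role is Role.ION:
                d = r - pos_bohr[i]
                dist = np.linalg.norm(d)
                E += atom.formal_charge * d / dist**3
        for o_idx, b in bisectors.items():
            if structure.atoms[o_idx].molecule_id == exclude_molecule:
                continue
            p = mu_int * b
            d = r - pos_bohr[o_idx]
            dist = np.linalg.norm(d)
            E += (3 * (p @ d) * d / dist**2 - p) / dist**3
        return E

    # 1. promolecule s populations
    shell_lists = {sym: basis.shells(sym) for sym in set(structure.symbols)}
    for i, atom, shell, sl in coeffs.iter_blocks():
        if shell.l != 0:
            continue
        exps = np.array([s.exponent for s in shell_lists[atom.element.symbol] if s.l == 0])
        z_eff = atom.element.atomic_number - atom.formal_charge
        pops = _s_populations(z_eff, exps)
        k = [s for s in shell_lists[atom.element.symbol] if s.l == 0].index(shell)
        values[sl.start] = pops[k] / shell.population_factor

    # 2. dipole terms on the most diffuse p shell
    def add_dipole(atom_index: int, mu_vec: np.ndarray) -> None:
        atom = structure.atoms[atom_index]
        shells = shell_lists[atom.element.symbol]
        p_shells = [s for s in shells if s.l == 1]
        if not p_shells:
            raise ValueError(f"Element {atom.element.symbol} has no p shells in basis {basis.name!r}.")
        target = min(p_shells, key=lambda s: s.exponent)
        for i, a, shell, sl in coeffs.iter_blocks():
            if i == atom_index and shell is target:
                t = shell.first_moment_factor
                # electronic moment enters the dipole with a minus sign;
                # components are ordered (y, z, x)
                values[sl] += (-1.0 / t) * np.array([mu_vec[1], mu_vec[2], mu_vec[0]])
                return

    for o_idx, b in bisectors.items():
        mol = structure.atoms[o_idx].molecule_id
        mu = mu_int * b
        if params.water_polarizability > 0:
            mu = mu + params.water_polarizability * field_at(pos_bohr[o_idx], exclude_molecule=mol)
        add_dipole(o_idx, mu)

    if params.solute_polarizability > 0:
        for i, atom in enumerate(structure.atoms):
            if atom.role in (Role.WATER, Role.ION) or atom.element.is_hydrogen:
                continue
            E = field_at(pos_bohr[i], exclude_molecule=atom.molecule_id)
            if np.any(E):
                add_dipole(i, params.solute_polarizability * E)

    return DensityCoefficients(structure, basis, values)


# ===========================================================================
# Datasets and manifests
# ===========================================================================
def make_dataset(
    spec: list[dict],
    params: MockOracleParams,
    basis: AuxBasis,
    seed: int = 0,
) -> tuple[list[tuple[Structure, DensityCoefficients]], dict[str, list[int]]]:
    """Generate (structure, population-normalised coefficients) pairs.

    ``spec`` is a list of entries like
    ``{"kind": "water_cluster", "count": 10, "n_waters": 1}``; recognised
    kinds are those of :func:`make_solvated_system` plus ``bdna_step``
    (requires ``"sequence"``).  Returns the pairs and a deterministic
    80/10/10 train/val/test index split.
    """
    rng = np.random.default_rng(seed)
    pairs: list[tuple[Structure, DensityCoefficients]] = []
    for entry in spec:
        kind = entry["kind"]
        for c in range(int(entry["count"])):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            if kind == "bdna_step":
                s = make_bdna_step(entry["sequence"], n_waters=entry.get("n_waters", 0), seed=sub_seed,
                                   mg_bound=entry.get("mg_bound", False))
            elif kind in ("water_cluster", "mg_shell", "cl_shell", "solvated_fragment"):
                s = make_solvated_system(kind, entry.get("n_waters", 1), seed=sub_seed)
            else:
                raise ValueError(f"Unknown dataset kind {kind!r}.")
            if entry.get("random_orientation", True):
                R = _random_rotation(rng)
                s = s.transformed(R, rng.normal(scale=entry.get("jitter", 0.0) or 1e-12, size=3))
            raw = mock_dft_coefficients(s, params, basis)
            pairs.append((s, normalize_populations(raw, "to_normalized")))
    order = rng.permutation(len(pairs))
    n = len(pairs)
    n_train = max(1, int(round(0.8 * n)))
    n_val = max(0, int(round(0.1 * n)))
    splits = {
        "train": sorted(order[:n_train].tolist()),
        "val": sorted(order[n_train : n_train + n_val].tolist()),
        "test": sorted(order[n_train + n_val :].tolist()),
    }
    return pairs, splits


def combined_test_manifest(per_class: int = 10, n_waters: int = 100) -> list[dict]:
    """The combined DNA-solvent model test-set manifest.

    Ten solvated structures for each of the ten unique base-pair steps,
    plus ten structures with Mg2+ bound to the phosphate: 110 entries.
    """
    from .fragments import enumerate_steps

    _, unique = enumerate_steps()
    entries = []
    for step in unique:
        for r in range(per_class):
            entries.append({"kind": "bdna_step", "sequence": step, "n_waters": n_waters, "replicate": r})
    for r in range(per_class):
        entries.append({"kind": "bdna_step", "sequence": unique[0], "n_waters": n_waters,
                        "mg_bound": True, "replicate": r})
    return entries
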