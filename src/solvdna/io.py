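"""Structure file I/O: PDB (via biotite) and XYZ.

Snapshots arrive as single-model PDB or XYZ files.  On reading a PDB,
residues named WAT/HOH/SPC/TIP3 (and passing a 1 O + 2 H composition check)
are tagged ``role=water``, single-atom MG/CL residues ``role=ion``, and
everything else ``role=DNA``.  Cap hydrogens written by the fragmenter use
the reserved atom name ``HCAP`` so that capping provenance survives a
round trip.

XYZ files carry no residue information, so each connected molecule gets its
own molecule id and roles are inferred from composition: isolated Mg/Cl
atoms become ions, O+2H molecules become water, the rest DNA.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .elements import get_element
from .structure import Atom, Role, Structure, assign_roles

CAP_ATOM_NAME = "HCAP"


def _role_for_residue(res_name: str, members: list[tuple[str, str]]) -> tuple[Role, int]:
    return assign_roles(res_name, members)


def read_pdb(path: str | os.PathLike) -> Structure:
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        array = pdb.get_structure(model=1)
    except Exception as exc:  # biotite raises several parse-error types
        raise ValueError(f"Unparsable PDB file {path}: {exc}") from exc
    if array.array_length() == 0:
        raise ValueError(f"PDB file {path} contains no atoms.")

    # Group into residues by (chain, res_id, insertion) in file order.
    keys = list(zip(array.chain_id, array.res_id, array.ins_code))
    order: dict[tuple, int] = {}
    for k in keys:
        order.setdefault(k, len(order))
    mol_ids = [order[k] for k in keys]

    # Element symbols: prefer the element column, fall back to the atom name.
    atoms: list[Atom] = []
    residue_members: dict[int, list[tuple[str, str]]] = {}
    symbols = []
    for i in range(array.array_length()):
        sym = str(array.element[i]).strip()
        if not sym:
            sym = "".join(c for c in str(array.atom_name[i]) if c.isalpha())[:2]
        element = get_element(sym)  # raises on unknown symbol
        symbols.append(element.symbol)
        residue_members.setdefault(mol_ids[i], []).append(
            (str(array.atom_name[i]), element.symbol)
        )

    roles: dict[int, tuple[Role, int]] = {
        mid: _role_for_residue(str(array.res_name[idx]), residue_members[mid])
        for mid, idx in {m: i for i, m in enumerate(mol_ids)}.items()
    }

    for i in range(array.array_length()):
        role, charge = roles[mol_ids[i]]
        name = str(array.atom_name[i]).strip()
        if name == CAP_ATOM_NAME:
            role, charge = Role.CAP, 0
        atoms.append(
            Atom(
                element=get_element(symbols[i]),
                position=np.asarray(array.coord[i], dtype=float),
                role=role,
                molecule_id=mol_ids[i],
                atom_name=name,
                residue_name=str(array.res_name[i]).strip(),
                formal_charge=charge,
            )
        )
    return Structure(atoms, label=Path(path).stem, provenance={"source": str(path), "format": "PDB"})


def write_pdb(structure: Structure, path: str | os.PathLike) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(structure)
    array = struc.AtomArray(n)
    array.coord = structure.positions.astype(np.float32)
    res_ids = {}
    for i, atom in enumerate(structure.atoms):
        res_ids.setdefault(atom.molecule_id, len(res_ids) + 1)
        array.chain_id[i] = "A"
        array.res_id[i] = res_ids[atom.molecule_id]
        array.res_name[i] = atom.residue_name or _default_residue_name(atom)
        array.atom_name[i] = (CAP_ATOM_NAME if atom.role is Role.CAP else atom.atom_name) or atom.element.symbol
        array.element[i] = atom.element.symbol
        array.hetero[i] = atom.role in (Role.WATER, Role.ION)
    pdb = PDBFile()
    pdb.set_structure(array)
    pdb.write(str(path))


def _default_residue_name(atom: Atom) -> str:
    if atom.role is Role.WATER:
        return "WAT"
    if atom.role is Role.ION:
        return atom.element.symbol.upper()
    return "UNK"


def read_xyz(path: str | os.PathLike) -> Structure:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"Unparsable XYZ file {path}: empty file (line 1)")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"Unparsable XYZ file {path}: line 1 is not an atom count") from None
    if len(lines) < n + 2:
        raise ValueError(f"Unparsable XYZ file {path}: expected {n} atom lines, file ends at line {len(lines)}")
    symbols, coords = [], []
    for ln, line in enumerate(lines[2 : n + 2], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"Unparsable XYZ file {path}: malformed atom record at line {ln}")
        element = get_element(parts[0])
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise ValueError(f"Unparsable XYZ file {path}: non-numeric coordinate at line {ln}") from None
        symbols.append(element)
        coords.append(xyz)

    # Infer molecules from covalent connectivity, then roles from composition.
    coords = np.array(coords)
    mol_of = _connected_components(symbols, coords)
    atoms = []
    for i, (el, pos) in enumerate(zip(symbols, coords)):
        members = [j for j in range(len(symbols)) if mol_of[j] == mol_of[i]]
        syms = sorted(symbols[j].symbol for j in members)
        if len(members) == 1 and el.symbol in ("Mg", "Cl"):
            role, charge = Role.ION, {"Mg": 2, "Cl": -1}[el.symbol]
        elif syms == ["H", "H", "O"]:
            role, charge = Role.WATER, 0
        else:
            role, charge = Role.DNA, 0
        atoms.append(Atom(el, pos, role, mol_of[i], atom_name=el.symbol, formal_charge=charge))
    return Structure(atoms, label=Path(path).stem, provenance={"source": str(path), "format": "XYZ"})


def _connected_components(elements, coords: np.ndarray) -> list[int]:
    """Molecule ids from the geometric bond rule d < 1.2 (r_i + r_j)."""
    n = len(elements)
    radii = np.array([e.covalent_radius for e in elements])
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if n > 1:
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        cut = 1.2 * (radii[:, None] + radii[None, :])
        for i in range(n):
            for j in range(i + 1, n):
                if d[i, j] < cut[i, j]:
                    parent[find(i)] = find(j)
    roots = {}
    out = []
    for i in range(n):
        r = find(i)
        roots.setdefault(r, len(roots))
        out.append(roots[r])
    return out


def write_xyz(structure: Structure, path: str | os.PathLike, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(structure)}\n{comment or structure.label}\n")
        for atom in structure.atoms:
            x, y, z = atom.position
            fh.write(f"{atom.element.symbol:<2s} {x:15.8f} {y:15.8f} {z:15.8f}\n")


def read_structure(path: str | os.PathLike, fmt: str | None = None) -> Structure:
    """Read a structure, inferring the format from the extension if not given."""
    fmt = (fmt or Path(path).suffix.lstrip(".")).lower()
    if fmt == "pdb":
        return read_pdb(path)
    if fmt == "xyz":
        return read_xyz(path)
    raise ValueError(f"Unsupported structure format {fmt!r} (PDB and XYZ are supported).")


def write_structure(structure: Structure, path: str | os.PathLike, fmt: str | None = None) -> None:
    fmt = (fmt or Path(path).suffix.lstrip(".")).lower()
    if fmt == "pdb":
        write_pdb(structure, path)
    elif fmt == "xyz":
        write_xyz(structure, path)
    else:
        raise ValueError(f"Unsupported structure format {fmt!r} (PDB and XYZ are supported).")
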