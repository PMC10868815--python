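"""Base-pair-step enumeration and fragmentation into training structures.

A duplex training unit (two stacked Watson-Crick pairs plus solvent) is
cut into the fragment categories used to train the density model:

* ``dna_only`` — per step: 2 base-pair fragments, 2 same-strand
  base-stacking fragments and 4 nucleotide fragments (8 in total);
* ``dna_with_solvent`` — each distinct nucleobase with its 12 nearest
  waters, and sugar-phosphate backbone fragments with 12 waters, flagged
  (and including the ion) when an Mg2+ is bound to a phosphate oxygen at
  under 2 Angstrom;
* solvent-only classes (Mg2+ shells, Cl- shells, water clusters) are
  generated directly by :mod:`solvdna.synth` rather than cut from steps.

Every dangling bond produced by a cut is capped with a hydrogen placed
along the former bond direction at the kept atom's standard X-H length.
Bonds are detected geometrically (d < 1.2 x sum of covalent radii), which
keeps the cutter independent of any particular topology dictionary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .elements import get_element
from .structure import Atom, Role, Structure

# ---------------------------------------------------------------------------
# base-pair-step enumeration
# ---------------------------------------------------------------------------
_BASE_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: fragments per base-pair step in the dna_only scheme
DNA_ONLY_FRAGMENTS_PER_STEP = 8
#: solvent-only training classes
SOLVENT_ONLY_CLASSES = ("mg_shell", "cl_shell", "water_cluster")
#: DNA-with-solvent training classes (four bases, backbone with/without Mg)
DNA_WITH_SOLVENT_CLASSES = ("base_A", "base_C", "base_G", "base_T", "backbone", "backbone_mg")


@dataclass(frozen=True)
class BasePairStep:
    """A 2-letter base-pair step (5'->3' on the reference strand)."""

    sequence: str
    canonical_form: str


def reverse_complement(sequence: str) -> str:
    return "".join(_BASE_COMPLEMENT[b] for b in reversed(sequence.upper()))


def canonical_step(sequence: str) -> str:
    """Representative of a step's symmetry class.

    Reading the complementary strand 5'->3' turns step XY into its
    reverse complement, so both describe the same duplex; the
    lexicographic minimum of the two is the canonical form.
    """
    sequence = sequence.upper()
    if len(sequence) != 2 or any(b not in _BASE_COMPLEMENT for b in sequence):
        raise ValueError(f"A base-pair step is 2 letters over ACGT, got {sequence!r}.")
    return min(sequence, reverse_complement(sequence))


def enumerate_steps() -> tuple[list[BasePairStep], list[str]]:
    """All 16 base-pair step sequences and the 10 unique symmetry classes."""
    all_steps = [
        BasePairStep(a + b, canonical_step(a + b))
        for a, b in itertools.product("ACGT", repeat=2)
    ]
    unique = sorted({s.canonical_form for s in all_steps})
    return all_steps, unique


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------
FRAGMENT_CATEGORIES = (
    "base_pair",
    "base_stacking",
    "nucleotide",
    "base_with_solvent",
    "backbone_with_solvent",
    "ion_shell",
    "water_cluster",
)


@dataclass
class Fragment:
    """A capped training fragment cut from a parent structure."""

    structure: Structure
    category: str
    capped_atoms: list[tuple[Atom, int]] = field(default_factory=list)
    parent_label: str = ""
    mg_bound: bool = False

    def __post_init__(self) -> None:
        if self.category not in FRAGMENT_CATEGORIES:
            raise ValueError(f"Unknown fragment category {self.category!r}.")
        for cap, _ in self.capped_atoms:
            if not (cap.element.is_hydrogen and cap.role is Role.CAP):
                raise ValueError("Cap atoms must be hydrogens with role=cap.")


def detect_bonds(structure: Structure) -> list[tuple[int, int]]:
    """Covalent bonds by the geometric rule d < 1.2 (r_i + r_j)."""
    pos = structure.positions
    radii = np.array([a.element.covalent_radius for a in structure.atoms])
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    cut = 1.2 * (radii[:, None] + radii[None, :])
    ii, jj = np.where((d < cut) & (d > 0))
    return [(int(i), int(j)) for i, j in zip(ii, jj) if i < j]


def cap_dangling_bonds(
    fragment: Fragment,
    parent: Structure,
    bonds: list[tuple[int, int]] | None = None,
) -> Fragment:
    """Cap every severed heavy-atom bond of ``fragment`` with a hydrogen.

    The fragment's atoms must be a subset of ``parent`` (recorded in its
    ``provenance['indices']``).  For each parent bond between a kept heavy
    atom X and a removed heavy atom Y, an H is placed along X->Y at X's
    standard X-H bond length.  Severed bonds to removed hydrogens are
    ignored.
    """
    indices = fragment.structure.provenance.get("indices")
    if indices is None:
        raise ValueError("Fragment does not record its parent atom indices; use Structure.subset().")
    kept = {int(p): k for k, p in enumerate(indices)}
    if bonds is None:
        bonds = detect_bonds(parent)
    new_atoms = list(fragment.structure.atoms)
    capped = list(fragment.capped_atoms)
    positions = fragment.structure.positions
    for i, j in bonds:
        for x, y in ((i, j), (j, i)):
            if x in kept and y not in kept:
                ax, ay = parent.atoms[x], parent.atoms[y]
                if ax.element.is_hydrogen or ay.element.is_hydrogen:
                    continue
                direction = ay.position - ax.position
                direction /= np.linalg.norm(direction)
                cap_pos = ax.position + ax.element.standard_XH_bond_length * direction
                clash = np.linalg.norm(positions - cap_pos, axis=1).min()
                if clash < 0.7:
                    k = int(np.argmin(np.linalg.norm(positions - cap_pos, axis=1)))
                    raise ValueError(
                        f"Cap for severed bond {ax.atom_name}-{ay.atom_name} would clash "
                        f"({clash:.2f} A) with fragment atom {fragment.structure.atoms[k].atom_name}."
                    )
                cap = Atom(
                    get_element("H"),
                    cap_pos,
                    Role.CAP,
                    ax.molecule_id,
                    atom_name="HCAP",
                    residue_name=ax.residue_name,
                )
                new_atoms.append(cap)
                capped.append((cap, int(y)))
    structure = Structure(new_atoms, label=fragment.structure.label, provenance=dict(fragment.structure.provenance))
    return Fragment(structure, fragment.category, capped, fragment.parent_label, fragment.mg_bound)


def extract_solvent_shell(
    structure: Structure,
    solute_atom_indices: list[int],
    n_waters: int,
    category: str = "base_with_solvent",
) -> Fragment:
    """Solute plus its ``n_waters`` nearest whole water molecules.

    Distance of a water is the minimum O-to-solute-atom distance; ties are
    broken by original molecule order.  Waters are never split.
    """
    waters = structure.water_molecules()
    if len(waters) < n_waters:
        raise ValueError(
            f"Requested {n_waters} waters but the structure contains only {len(waters)}."
        )
    solute_pos = structure.positions[list(solute_atom_indices)]
    ranked = []
    for rank, group in enumerate(waters):
        o_idx = next(i for i in group if structure.atoms[i].element.symbol == "O")
        dist = float(np.linalg.norm(solute_pos - structure.atoms[o_idx].position, axis=1).min())
        ranked.append((dist, rank, group))
    ranked.sort(key=lambda t: (t[0], t[1]))
    chosen = [i for _, _, group in ranked[:n_waters] for i in group]
    indices = list(solute_atom_indices) + chosen
    sub = structure.subset(indices, label=f"{structure.label}-shell{n_waters}")
    return Fragment(sub, category, parent_label=structure.label)


def filter_mg_bound(structure: Structure, cutoff: float = 2.0) -> list[tuple[int, int]]:
    """(Mg index, phosphate-O index) pairs closer than ``cutoff`` Angstrom.

    Phosphate oxygens are the O atoms named OP1/OP2/OP3/O5'/O3' of DNA
    residues (i.e. the oxygens bonded to P in the backbone).
    """
    mg = [i for i, a in enumerate(structure.atoms) if a.element.symbol == "Mg"]
    phos_o = [
        i
        for i, a in enumerate(structure.atoms)
        if a.role is Role.DNA
        and a.element.symbol == "O"
        and a.atom_name in ("OP1", "OP2", "OP3", "O5'", "O3'")
    ]
    pairs = []
    for i in mg:
        for j in phos_o:
            if np.linalg.norm(structure.atoms[i].position - structure.atoms[j].position) < cutoff:
                pairs.append((i, j))
    return pairs


# ---------------------------------------------------------------------------
# residue bookkeeping for duplex steps
# ---------------------------------------------------------------------------
_PHOSPHATE_NAMES = {"P", "OP1", "OP2", "OP3"}


def _residue_parts(structure: Structure, mol_id: int) -> dict[str, list[int]]:
    """Split a DNA residue's atom indices into base / sugar / phosphate."""
    idx = structure.atoms_of_molecule(mol_id)
    parts = {"base": [], "sugar": [], "phosphate": []}
    for i in idx:
        name = structure.atoms[i].atom_name
        if name in _PHOSPHATE_NAMES:
            parts["phosphate"].append(i)
        elif "'" in name:
            parts["sugar"].append(i)
        else:
            parts["base"].append(i)
    return parts


def _dna_residues(structure: Structure) -> list[int]:
    return [
        mid
        for mid in structure.molecule_ids()
        if all(structure.atoms[i].role in (Role.DNA, Role.CAP) for i in structure.atoms_of_molecule(mid))
        and any(structure.atoms[i].atom_name == "C1'" for i in structure.atoms_of_molecule(mid))
    ]


def _strands(structure: Structure, residues: list[int], bonds: list[tuple[int, int]]) -> list[list[int]]:
    """Group residues into strands via O3'-P junction bonds, 5'->3' order."""
    succ: dict[int, int] = {}
    for i, j in bonds:
        a, b = structure.atoms[i], structure.atoms[j]
        for x, y in ((a, b), (b, a)):
            if x.atom_name == "O3'" and y.atom_name == "P" and x.molecule_id != y.molecule_id:
                succ[x.molecule_id] = y.molecule_id
    preds = set(succ.values())
    strands = []
    for start in residues:
        if start in preds:
            continue
        chain = [start]
        while chain[-1] in succ:
            chain.append(succ[chain[-1]])
        strands.append(chain)
    return strands


def _glycosidic_n(structure: Structure, mol_id: int) -> str:
    names = {structure.atoms[i].atom_name for i in structure.atoms_of_molecule(mol_id)}
    return "N9" if "N9" in names else "N1"


def _wc_atom_index(structure: Structure, mol_id: int) -> int:
    """Index of the central Watson-Crick hydrogen-bond atom (purine N1, pyrimidine N3)."""
    purine = _glycosidic_n(structure, mol_id) == "N9"
    target = "N1" if purine else "N3"
    return next(
        i for i in structure.atoms_of_molecule(mol_id) if structure.atoms[i].atom_name == target
    )


def watson_crick_pairs(structure: Structure) -> list[tuple[int, int]]:
    """Pair residues across strands by the N1...N3 hydrogen-bond distance."""
    residues = _dna_residues(structure)
    bonds = detect_bonds(structure)
    strands = _strands(structure, residues, bonds)
    if len(strands) != 2:
        raise ValueError(f"Expected a duplex with 2 strands, found {len(strands)}.")
    s1, s2 = strands
    pairs = []
    for r1 in s1:
        i1 = _wc_atom_index(structure, r1)
        best = min(
            s2,
            key=lambda r2: np.linalg.norm(
                structure.atoms[i1].position - structure.atoms[_wc_atom_index(structure, r2)].position
            ),
        )
        d = np.linalg.norm(
            structure.atoms[i1].position - structure.atoms[_wc_atom_index(structure, best)].position
        )
        if d > 3.5:
            raise ValueError(f"No Watson-Crick partner found for residue {r1} (closest N..N {d:.2f} A).")
        pairs.append((r1, best))
    if len({p[1] for p in pairs}) != len(pairs):
        raise ValueError("Watson-Crick pairing is not one-to-one; malformed duplex.")
    return pairs


# ---------------------------------------------------------------------------
# the fragmentation schemes
# ---------------------------------------------------------------------------
def fragment_base_pair_step(
    solvated_step: Structure,
    scheme: str,
    n_waters: int = 12,
    mg_cutoff: float = 2.0,
) -> list[Fragment]:
    """Cut a (solvated) base-pair step into training fragments.

    ``scheme='dna_only'`` gives the 8 DNA fragments of a step (2 base
    pairs, 2 base stackings, 4 nucleotides).  ``scheme='dna_with_solvent'``
    gives one fragment per distinct base with its 12 nearest waters plus
    one sugar-phosphate backbone fragment per residue with 12 waters,
    Mg-flagged according to :func:`filter_mg_bound`.
    """
    if scheme not in ("dna_only", "dna_with_solvent"):
        raise ValueError(f"Unknown fragmentation scheme {scheme!r}.")
    bonds = detect_bonds(solvated_step)
    pairs = watson_crick_pairs(solvated_step)
    if len(pairs) != 2:
        raise ValueError(f"A base-pair step has exactly 2 base pairs, found {len(pairs)}.")
    residues = _dna_residues(solvated_step)
    strands = _strands(solvated_step, residues, bonds)
    label = solvated_step.label
    fragments: list[Fragment] = []

    def capped_subset(indices: list[int], category: str, name: str) -> Fragment:
        sub = solvated_step.subset(sorted(indices), label=f"{label}-{name}")
        frag = Fragment(sub, category, parent_label=label)
        return cap_dangling_bonds(frag, solvated_step, bonds)

    if scheme == "dna_only":
        for k, (r1, r2) in enumerate(pairs):
            idx = _residue_parts(solvated_step, r1)["base"] + _residue_parts(solvated_step, r2)["base"]
            fragments.append(capped_subset(idx, "base_pair", f"pair{k}"))
        for k, strand in enumerate(strands):
            idx = [i for r in strand for i in _residue_parts(solvated_step, r)["base"]]
            fragments.append(capped_subset(idx, "base_stacking", f"stack{k}"))
        for r in residues:
            idx = solvated_step.atoms_of_molecule(r)
            letter = solvated_step.atoms[idx[0]].residue_name[-1]
            fragments.append(capped_subset(idx, "nucleotide", f"nuc-{letter}{r}"))
        return fragments

    # dna_with_solvent
    mg_pairs = filter_mg_bound(solvated_step, cutoff=mg_cutoff)
    mg_bound_residues = {solvated_step.atoms[j].molecule_id for _, j in mg_pairs}
    seen_letters: set[str] = set()
    for r in residues:
        letter = solvated_step.atoms[solvated_step.atoms_of_molecule(r)[0]].residue_name[-1]
        if letter in seen_letters:
            continue
        seen_letters.add(letter)
        base_idx = _residue_parts(solvated_step, r)["base"]
        shell = extract_solvent_shell(solvated_step, base_idx, n_waters, category="base_with_solvent")
        frag = cap_dangling_bonds(shell, solvated_step, bonds)
        frag.structure.label = f"{label}-base{letter}"
        fragments.append(frag)
    for r in residues:
        parts = _residue_parts(solvated_step, r)
        idx = parts["sugar"] + parts["phosphate"]
        bound = r in mg_bound_residues
        if bound:
            idx = idx + [i for i, j in mg_pairs if solvated_step.atoms[j].molecule_id == r]
        shell = extract_solvent_shell(solvated_step, idx, n_waters, category="backbone_with_solvent")
        frag = cap_dangling_bonds(shell, solvated_step, bonds)
        frag.structure.label = f"{label}-backbone{r}"
        frag.mg_bound = bound
        fragments.append(frag)
    return fragments


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------
@dataclass
class Manifest:
    """Per-class fragment counts of a training set."""

    entries: list[tuple[str, str, int]]  # (category, class, count)

    @property
    def total(self) -> int:
        return sum(c for _, _, c in self.entries)

    def totals_by_category(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for cat, _, c in self.entries:
            out[cat] = out.get(cat, 0) + c
        return out

    def to_rows(self) -> list[dict]:
        return [{"category": c, "class": k, "count": n} for c, k, n in self.entries]


def build_manifest(snapshot_set: list[Structure], schemes: tuple[str, ...] = ("dna_only",)) -> Manifest:
    """Tabulate fragment classes and counts for a labelled snapshot set.

    DNA snapshots must carry their canonical step in
    ``provenance['step']``; solvent-only snapshots carry their class kind
    in ``provenance['kind']``.
    """
    entries: dict[tuple[str, str], int] = {}
    if "solvent_only" in schemes:
        for klass in SOLVENT_ONLY_CLASSES:
            entries[("solvent_only", klass)] = 0
    for s in snapshot_set:
        kind = s.provenance.get("kind")
        if kind in SOLVENT_ONLY_CLASSES:
            if "solvent_only" in schemes:
                entries[("solvent_only", kind)] += 1
            continue
        step = s.provenance.get("step")
        if step is None:
            raise ValueError(f"Snapshot {s.label!r} has no step label (provenance['step']).")
        step = canonical_step(step)
        if "dna_only" in schemes:
            key = ("dna_only", step)
            entries[key] = entries.get(key, 0) + DNA_ONLY_FRAGMENTS_PER_STEP
        if "dna_with_solvent" in schemes:
            for klass in DNA_WITH_SOLVENT_CLASSES:
                key = ("dna_with_solvent", klass)
                entries[key] = entries.get(key, 0)
            frags = fragment_base_pair_step(s, "dna_with_solvent")
            for f in frags:
                if f.category == "base_with_solvent":
                    klass = "base_" + f.structure.label[-1]
                else:
                    klass = "backbone_mg" if f.mg_bound else "backbone"
                entries[("dna_with_solvent", klass)] += 1
    return Manifest([(c, k, n) for (c, k), n in sorted(entries.items())])
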