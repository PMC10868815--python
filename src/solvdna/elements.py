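"""Element table and one-hot vocabularies.

The package works with the seven element types that occur in solvated DNA
with Mg2+/Cl- counterions: H, C, N, O, P, Mg, Cl.  A second, nine-type
vocabulary treats water hydrogens and oxygens ("HW", "OW") as element types
distinct from their DNA counterparts.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Element:
    """A chemical element as used throughout the package.

    Attributes
    ----------
    symbol : str
        Element symbol ("H", "C", ...).
    atomic_number : int
        Nuclear charge Z in units of e.
    one_hot_index : int
        Position of this element in the general (seven-type) one-hot
        vocabulary.
    covalent_radius : float
        Covalent radius in Angstrom, used for geometric bond detection.
    standard_XH_bond_length : float
        Standard X-H bond length in Angstrom, used when a severed bond on
        this element is capped with hydrogen.
    """

    symbol: str
    atomic_number: int
    one_hot_index: int
    covalent_radius: float
    standard_XH_bond_length: float

    @property
    def is_hydrogen(self) -> bool:
        return self.atomic_number == 1


# Covalent radii from the Cordero compilation; X-H bond lengths are the
# standard organic values (C-H 1.09, N-H 1.01, O-H 0.96).
ELEMENTS: dict[str, Element] = {
    "H": Element("H", 1, 0, 0.31, 0.74),
    "C": Element("C", 6, 1, 0.76, 1.09),
    "N": Element("N", 7, 2, 0.71, 1.01),
    "O": Element("O", 8, 3, 0.66, 0.96),
    "P": Element("P", 15, 4, 1.07, 1.42),
    "Mg": Element("Mg", 12, 5, 1.41, 1.70),
    "Cl": Element("Cl", 17, 6, 1.02, 1.27),
}

#: One-hot order of the general (seven element type) model.
GENERAL_VOCABULARY: tuple[str, ...] = ("H", "C", "N", "O", "P", "Mg", "Cl")

#: One-hot order of the "distinct waters" variant: water H and O atoms are
#: separate input channels (HW, OW) from DNA hydrogens/oxygens.
DISTINCT_WATERS_VOCABULARY: tuple[str, ...] = GENERAL_VOCABULARY + ("HW", "OW")

VOCABULARIES: dict[str, tuple[str, ...]] = {
    "general": GENERAL_VOCABULARY,
    "distinct_waters": DISTINCT_WATERS_VOCABULARY,
}


def get_element(symbol: str) -> Element:
    """Look up an element by symbol (case-normalised); raise on unknown."""
    key = symbol.strip()
    key = key[0].upper() + key[1:].lower() if key else key
    try:
        return ELEMENTS[key]
    except KeyError:
        raise KeyError(
            f"Unknown element symbol {symbol!r}: the model vocabulary covers "
            f"{sorted(ELEMENTS)} only."
        ) from None
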