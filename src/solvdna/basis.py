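"""Auxiliary (density-fitting) Gaussian basis.

The electron density is expanded in atom-centered primitive Gaussians
times real solid harmonics,

    rho(r) = sum_i sum_k sum_m  C_ikm  N_kl  S_lm(r - r_i)  exp(-a_kl |r - r_i|^2),

with one shell k of degree l and exponent a per entry in the element's
shell list.  Each function is normalised to unit self-overlap,

    integral (N S_lm exp(-a r^2))^2 dV = 1,

which for an s shell gives N = (2a/pi)^(3/4).

Basis definitions are read from a small JSON dialect
(``{"name": ..., "elements": {"O": [{"l": 0, "exponent": 12.5}, ...]}}``),
with exponents in Bohr^-2.  The package ships ``synthetic_jfit.json``, a
synthetic even-tempered s/p/d set (lmax=2) standing in for a universal
Coulomb-fitting basis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from math import gamma, pi
from pathlib import Path

import numpy as np

from .elements import Element, get_element
from .harmonics import LMAX, n_components


def self_overlap_norm(exponent: float, l: int) -> float:
    """Normalisation constant giving unit self-overlap for (exponent, l)."""
    if exponent <= 0:
        raise ValueError(f"Gaussian exponent must be positive, got {exponent}")
    overlap = (4 * pi / (2 * l + 1)) * gamma(l + 1.5) / (2.0 * (2.0 * exponent) ** (l + 1.5))
    return 1.0 / np.sqrt(overlap)


@dataclass(frozen=True)
class AuxShell:
    """One auxiliary shell: element, Gaussian exponent (Bohr^-2), degree l."""

    element: Element
    exponent: float
    l: int
    norm: float

    @classmethod
    def make(cls, element: Element, exponent: float, l: int) -> "AuxShell":
        if l > LMAX:
            raise ValueError(f"Shell degree l={l} exceeds the supported maximum {LMAX}.")
        return cls(element, float(exponent), int(l), self_overlap_norm(exponent, l))

    @property
    def n_components(self) -> int:
        return n_components(self.l)

    @property
    def population_factor(self) -> float:
        """Electrons contributed per unit coefficient (zero unless l=0)."""
        if self.l != 0:
            return 0.0
        return self.norm * (pi / self.exponent) ** 1.5

    @property
    def first_moment_factor(self) -> float:
        """integral of S_1m-component position moment per unit coefficient (l=1 only)."""
        if self.l != 1:
            return 0.0
        return self.norm * (pi / self.exponent) ** 1.5 / (2.0 * self.exponent)

    @property
    def normalization_scale(self) -> float:
        """Coefficient scale used by population normalisation.

        For l=0 this equals the population factor (so a normalised l=0
        coefficient is the electron count the function holds); l>0
        coefficients are scaled by the analogous moment-sized factor
        N (pi/a)^{3/2} (2a)^{-l/2} so that stored targets are O(1).
        """
        return self.norm * (pi / self.exponent) ** 1.5 / (2.0 * self.exponent) ** (self.l / 2.0)


class AuxBasis:
    """Per-element ordered shell lists."""

    def __init__(self, shells_by_element: dict[str, list[AuxShell]], name: str = ""):
        self.shells_by_element = shells_by_element
        self.name = name

    def shells(self, symbol: str) -> list[AuxShell]:
        try:
            return self.shells_by_element[symbol]
        except KeyError:
            raise KeyError(
                f"Auxiliary basis {self.name!r} defines no shells for element {symbol!r}."
            ) from None

    def n_functions(self, symbol: str) -> int:
        return sum(s.n_components for s in self.shells(symbol))

    @property
    def elements(self) -> list[str]:
        return list(self.shells_by_element)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AuxBasis):
            return NotImplemented
        return self.name == other.name and {
            el: [(s.exponent, s.l) for s in shells] for el, shells in self.shells_by_element.items()
        } == {el: [(s.exponent, s.l) for s in shells] for el, shells in other.shells_by_element.items()}

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "elements": {
                el: [{"l": s.l, "exponent": s.exponent} for s in shells]
                for el, shells in self.shells_by_element.items()
            },
        }


def _basis_from_dict(data: dict) -> AuxBasis:
    shells_by_element = {}
    for symbol, shell_list in data["elements"].items():
        element = get_element(symbol)
        shells = []
        for entry in shell_list:
            exponents = entry.get("exponents", [entry["exponent"]] if "exponent" in entry else None)
            if exponents is None:
                raise ValueError(f"Basis entry for {symbol} lacks an 'exponent'/'exponents' field.")
            for a in np.atleast_1d(exponents):
                shells.append(AuxShell.make(element, float(a), int(entry["l"])))
        shells_by_element[element.symbol] = shells
    return AuxBasis(shells_by_element, name=data.get("name", ""))


def load_aux_basis(path: str | Path) -> AuxBasis:
    """Load an auxiliary basis from a JSON basis file."""
    with open(path) as fh:
        data = json.load(fh)
    return _basis_from_dict(data)


def default_basis() -> AuxBasis:
    """The shipped synthetic even-tempered fitting basis (lmax=2)."""
    text = resources.files("solvdna.data").joinpath("synthetic_jfit.json").read_text()
    return _basis_from_dict(json.loads(text))
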