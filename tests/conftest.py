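import numpy as np
import pytest

from solvdna.basis import default_basis
from solvdna.elements import get_element
from solvdna.structure import Atom, Role, Structure
from solvdna.synth import MockOracleParams, make_solvated_system, mock_dft_coefficients


@pytest.fixture(scope="session")
def basis():
    return default_basis()


@pytest.fixture(scope="session")
def oracle_params():
    return MockOracleParams()


@pytest.fixture(scope="session")
def water_monomer():
    return make_solvated_system("water_cluster", 1, seed=42)


@pytest.fixture(scope="session")
def water_monomer_coeffs(water_monomer, oracle_params, basis):
    return mock_dft_coefficients(water_monomer, oracle_params, basis)


@pytest.fixture()
def toy_water():
    """Hand-placed water used in worked examples: O at the origin."""
    return Structure(
        [
            Atom(get_element("O"), [0.0, 0.0, 0.0], Role.WATER, 0, "O", "WAT"),
            Atom(get_element("H"), [0.96, 0.0, 0.0], Role.WATER, 0, "H1", "WAT"),
            Atom(get_element("H"), [-0.24, 0.93, 0.0], Role.WATER, 0, "H2", "WAT"),
        ],
        label="toy-water",
    )


def rigid_motion(seed):
    from solvdna.harmonics import random_rotation

    rng = np.random.default_rng(seed)
    return random_rotation(rng), rng.normal(scale=3.0, size=3)
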