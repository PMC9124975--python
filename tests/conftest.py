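import pytest

from fes2red.partition import PAPER_GEOMETRY, builtin_henry_table
from fes2red.thermo import Conditions, builtin_species_table


@pytest.fixture(scope="session")
def species_table():
    return builtin_species_table()


@pytest.fixture(scope="session")
def henry_table():
    return builtin_henry_table()


@pytest.fixture
def cond38():
    """Study conditions: pH 7, I = 0.05 M, 38 C."""
    return Conditions(temperature=311.15, pH=7.0, ionic_strength=0.05)


@pytest.fixture
def cond25():
    return Conditions(temperature=298.15, pH=7.0, ionic_strength=0.05)


@pytest.fixture(scope="session")
def geometry():
    """165 mL serum bottle with 75 mL medium at 2.5 bar, 38 C."""
    return PAPER_GEOMETRY
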