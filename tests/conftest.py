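"""Shared fixtures: small systems that exercise every pipeline stage cheaply."""

import pytest

from stardpd import fixtures
from stardpd.model import Box, SimulationParams, initialize_system


def pytest_collection_modifyitems(items):
    """Run the long end-to-end acceptance checks after the unit suite."""
    items.sort(key=lambda it: it.path.name == "test_acceptance.py")


@pytest.fixture(scope="session")
def default_params() -> SimulationParams:
    return SimulationParams(seed=12345)


@pytest.fixture(scope="session")
def small_fluid():
    """3000-bead pure solvent box (L=10, rho=3)."""
    return fixtures.make_ideal_fluid(L=10.0, seed=11)


@pytest.fixture(scope="session")
def shell_vesicle():
    """Idealised raspberry-vesicle fixture with exact interior ground truth."""
    return fixtures.make_hollow_vesicle(seed=21)


@pytest.fixture(scope="session")
def rod_fixture():
    return fixtures.make_rod(n_beads=20000, seed=22)


@pytest.fixture(scope="session")
def disk_fixture():
    return fixtures.make_disk(n_beads=20000, seed=23)


@pytest.fixture(scope="session")
def tiny_polymer_system(default_params):
    """~650-bead box with 3 molecules: cheapest full polymer system."""
    box = Box(6.0)
    state, topo = initialize_system(box, 0.1, default_params, seed=31)
    return state, topo
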