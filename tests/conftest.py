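import numpy as np
import pytest

from ccrics import (
    SimulationConfig,
    SpeciesSpec,
    default_geometry,
    simulate_stack,
)


@pytest.fixture(scope="session")
def geom64():
    return default_geometry(64, 64)


@pytest.fixture(scope="session")
def geom128():
    return default_geometry(128, 128)


@pytest.fixture(scope="session")
def sim_double_d10(geom128):
    """100 double-labeled particles, D = 10 um^2/s, 30 frames of 128x128.

    Shared across the fit-recovery, homogeneous-map and amplitude-law tests
    (it is the most expensive small simulation in the suite).
    """
    config = SimulationConfig(
        geometry=geom128,
        species=[SpeciesSpec("double", 100, 10.0, 50.0)],
        n_frames=30,
        seed=1,
    )
    return simulate_stack(config)


@pytest.fixture(scope="session")
def sim_independent_d10(geom128):
    """Independent green-only/red-only mixture matching sim_double_d10."""
    config = SimulationConfig(
        geometry=geom128,
        species=[
            SpeciesSpec("green_only", 100, 10.0, 50.0),
            SpeciesSpec("red_only", 100, 10.0, 50.0),
        ],
        n_frames=30,
        seed=7,
    )
    return simulate_stack(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
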