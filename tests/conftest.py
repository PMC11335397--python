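import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nichecast as nc

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> nc.RunConfig:
    return nc.RunConfig()


@pytest.fixture(scope="session")
def default_inputs(default_config) -> nc.SimulationInputs:
    """The full-size default synthetic domain (76x76, seed 1)."""
    return nc.prepare_synthetic_inputs(default_config, seed=1)


@pytest.fixture(scope="session")
def small_config() -> nc.RunConfig:
    """A 30x30 domain (600 km side) for fast end-to-end unit tests.

    Predator populations are scaled with domain area (30^2/76^2 ~ 0.156) so
    the scaled-down world keeps the full domain's demand-to-stock balance.
    """
    scale = 30 ** 2 / 76 ** 2
    return nc.RunConfig(
        grid={"nx": 30, "ny": 30},
        synthetic={
            "n_islands": 3,
            "n_colonies": 3,
            "margin_km": 160.0,
            "total_pairs": round(4.8e6 * scale),
        },
        scenario={
            "nb17": round(50_000 * scale),
            "nb21": round(343 * scale),
            "na21_pairs": round(4.8e6 * scale),
        },
        parameters=[
            {"name": "na21_pairs", "sd": 3e5 * scale},
            {"name": "nb17", "sd": 2500 * scale},
            {"name": "nb21", "sd": 50 * scale},
        ],
    )


@pytest.fixture(scope="session")
def small_inputs(small_config) -> nc.SimulationInputs:
    return nc.prepare_synthetic_inputs(small_config, seed=3)


@pytest.fixture()
def tiny_wm() -> nc.WaterMassGrid:
    """2x2 grid with a land cell, a shallow cell and two deep cells."""
    grid = nc.GridSpec(nx=2, ny=2)
    bathy = np.array([[0.0, 35.0], [500.0, 120.0]])
    return nc.build_water_masses(grid, bathy)
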