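"""Shared fixtures: a short-acquisition synthetic device used across modules.

The reference device geometry (1300 µm gel, two monolayers, three 120 µm
gaps, 2 µm/px, 30 s frames) is kept, but acquisitions are truncated to
10 min so the whole suite stays fast; the measurement window (t0 + 10
frames) is well inside that.
"""

import numpy as np
import pytest

from permchip import SimulationConfig, simulate_device, solve_diffusion


@pytest.fixture(scope="session")
def fast_config() -> SimulationConfig:
    return SimulationConfig(duration=600.0, seed=42)


@pytest.fixture(scope="session")
def fast_truth(fast_config):
    return simulate_device(fast_config)


@pytest.fixture(scope="session")
def fast_field(fast_config):
    return solve_diffusion(fast_config)


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """Single-gap, single-monolayer device for cheap Monte-Carlo loops."""
    return SimulationConfig(
        duration=420.0,
        n_monolayers=1,
        n_gaps=1,
        lumen_width=60.0,
        seed=7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
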