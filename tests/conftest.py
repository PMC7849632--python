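import numpy as np
import pytest

from gliomech import RadialGrid, SimulationParams


@pytest.fixture(scope="session")
def params() -> SimulationParams:
    return SimulationParams()


@pytest.fixture(scope="session")
def grid(params) -> RadialGrid:
    return RadialGrid.from_spacing(params.R_dom, 5.0e-3)


@pytest.fixture(scope="session")
def coarse_grid(params) -> RadialGrid:
    """Cheaper grid (dr = 10 μm) for short dynamical tests."""
    return RadialGrid.from_spacing(params.R_dom, 1.0e-2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240601)
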