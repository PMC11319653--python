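import numpy as np
import pytest

from nanomig import SystemParams


@pytest.fixture
def unit_params() -> SystemParams:
    """Two donors on the unit sphere with R0 = 2R (fast exchange)."""
    return SystemParams(2, radius=1.0, critical_radius=2.0, lifetime=1.0)


@pytest.fixture
def small_system() -> SystemParams:
    """A small system usable by both the dense oracle and the simulator."""
    return SystemParams.from_xi(8, 0.25)


@pytest.fixture
def time_grid() -> np.ndarray:
    return np.linspace(0.0, 5.0, 26)
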