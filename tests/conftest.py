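import numpy as np
import pytest

from masdyn.spin_sim import PowderScheme, PulseTiming
from masdyn.tensor_fit import build_grid


@pytest.fixture(scope="session")
def timing_small():
    """Shifted-pulse timing with a short dephasing-time list."""
    return PulseTiming.shifted(n_rotor_periods_list=(2, 4, 8, 12, 16, 24, 32))


@pytest.fixture(scope="session")
def powder_small():
    """Reduced orientation grid for fast unit tests."""
    return PowderScheme(89, 8)


@pytest.fixture(scope="session")
def small_grid(timing_small, powder_small):
    """Coarse simulation grid spanning flexible-to-intermediate tensors."""
    return build_grid(timing_small, 4000.0, 7000.0, 150.0, 0.25, powder_small)
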