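import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from suturesim import SimulationParams


@pytest.fixture
def tiny_params() -> SimulationParams:
    """Small, fast lattice for mechanics-level tests."""
    return SimulationParams(nx=48, ny=32, t_end=200.0, c=0.0, noise_amp=25.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
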