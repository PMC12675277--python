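import numpy as np
import pytest

from ckflux import KineticParams, SimulationDesign


@pytest.fixture
def noiseless_design():
    return SimulationDesign(time_grid=tuple(np.linspace(0.0, 900.0, 16)), noise_sd=0.0)


@pytest.fixture
def reference_params():
    """Kinetic parameters in the range the assays this package models produce."""
    return KineticParams(I=5e-3, E=2e-3, K=0.01)


def random_param_sets(n, seed):
    """Random (I, E, K, f) draws spanning the physically plausible ranges."""
    rng = np.random.default_rng(seed)
    I = 10 ** rng.uniform(-4, -1, n)
    E = 10 ** rng.uniform(-4, -1, n)
    K = rng.uniform(0.0, 0.3, n)
    f = 10 ** rng.uniform(-3, np.log10(0.2), n)
    return I, E, K, f
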