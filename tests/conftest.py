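import numpy as np
import pytest
from hypothesis import settings

from teapigments.synthetic import SimConfig, simulate

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """30-sample rolling run (10 time points x 3 replicates), fixed seed."""
    return simulate(SimConfig(n_replicates=3, seed=7))


@pytest.fixture(scope="session")
def full_sim():
    """Full-scale 150-sample rolling run, fixed seed."""
    return simulate(SimConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
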