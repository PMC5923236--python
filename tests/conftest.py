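import numpy as np
import pytest

from edgeclust import synthetic as syn


@pytest.fixture(scope="session")
def small_velocity_set():
    """20 series per phenotype at 5%-of-amplitude noise; fixed seed."""
    return syn.generate_velocity_set(20, 2.0, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
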