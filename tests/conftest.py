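import numpy as np
import pytest

from fetalsweep.phantom import PhantomConfig, make_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One deterministic cephalic/anterior phantom shared across tests."""
    config = PhantomConfig(seed=7)
    exam, truth = make_phantom(config)
    return config, exam, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
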