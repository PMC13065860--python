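import numpy as np
import pytest

from mammoiq import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def dm():
    return synthetic.dm_preset()


@pytest.fixture(scope="session")
def sm():
    return synthetic.sm_preset()


@pytest.fixture(scope="session")
def dm_flat_stack(dm):
    """10 repeated DM-like flat-field acquisitions (session-cached)."""
    stack, truth = synthetic.gen_flat_stack(dm.flat_config(n_images=10, seed=11))
    return stack, truth


@pytest.fixture(scope="session")
def sm_flat_stack(sm):
    stack, truth = synthetic.gen_flat_stack(sm.flat_config(n_images=10, seed=11))
    return stack, truth
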