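import numpy as np
import pytest

import statesync as ss


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def state_dataset():
    """A moderately sized latent-state dataset with ground truth, shared
    across tests that only read from it."""
    return ss.simulate_state_dataset(n_subjects=10, T=300, V=40, k=4, seed=7)
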