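import numpy as np
import pytest

from fisseg.synthetic import generate_case, make_dataset


@pytest.fixture(scope="session")
def case64():
    """One deterministic 64^3 toy case shared across tests."""
    return generate_case(seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """Two labeled keypoint clouds (desk-scale density)."""
    return make_dataset(2, seed=11, k_max=4096)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
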