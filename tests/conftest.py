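import numpy as np
import pytest

from lipidflux import default_model, find_steady_state
from lipidflux.synth import SyntheticSpec, generate_steady_state_dataset


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def baseline_ss(model):
    ss = find_steady_state(model)
    assert ss.converged
    return ss


@pytest.fixture(scope="session")
def synthetic_dataset():
    """One representative synthetic condition table + planted truth."""
    return generate_steady_state_dataset(SyntheticSpec(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
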