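import numpy as np
import pytest
from hypothesis import settings

import copdsim as cs

# one deterministic profile for the whole suite
settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def true_model():
    return cs.default_true_model()


@pytest.fixture(scope="session")
def small_cohort():
    return cs.generate_baseline(seed=11, n=400)


@pytest.fixture(scope="session")
def small_trajectories(small_cohort, true_model):
    return cs.generate_histories(small_cohort, true_model, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
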