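import numpy as np
import pytest

from dcmnet import design, model_space, synthetic


@pytest.fixture(scope="session")
def default_session():
    """The full 6-run block design (seeded condition orders)."""
    return design.default_session(seed=0)


@pytest.fixture(scope="session")
def one_run_session():
    return design.default_session(n_runs=1, seed=0)


@pytest.fixture(scope="session")
def space():
    return model_space.enumerate_models()


@pytest.fixture(scope="session")
def model1(space):
    return space[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def stable_params():
    """A stable, deterministic parameter set on the generating model."""
    truth = synthetic.default_truth(n_subjects=1, snr=3.0, seed=0)
    return truth.mean
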