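import numpy as np
import pytest

from emodeg import SETTINGS, ModelParameters, generate_setting


@pytest.fixture(scope="session")
def setting1_params() -> ModelParameters:
    return SETTINGS[1].params


@pytest.fixture(scope="session")
def setting2_params() -> ModelParameters:
    return SETTINGS[2].params


@pytest.fixture(scope="session")
def small_dataset():
    """10 Setting-1 sequences of 21 observations, fixed seed."""
    return generate_setting(1, seed=3, n_sequences=10)


@pytest.fixture(scope="session")
def tiny_dataset():
    """2 Setting-1 sequences of 4 observations, for oracle comparisons."""
    return generate_setting(1, seed=11, n_sequences=2, n_obs=4)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
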