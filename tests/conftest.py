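import numpy as np
import pytest

from cprharvest.params import DEFAULT_INIT, ModelParams


@pytest.fixture(scope="session")
def defaults() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def init():
    return DEFAULT_INIT


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
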