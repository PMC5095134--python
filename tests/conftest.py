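import numpy as np
import pytest

from conductrace import ModelParams


@pytest.fixture
def params():
    """Standard-protocol constants with a short grid for fast tests."""
    return ModelParams(T=200)


@pytest.fixture
def params_tiny():
    return ModelParams(T=8)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
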