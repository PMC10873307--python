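import numpy as np
import pytest

from remstim.types import Hypnogram


@pytest.fixture
def all_rem_hypnogram():
    """10 minutes of uninterrupted REM."""
    return Hypnogram(stages=["R"] * 20)


@pytest.fixture
def all_n2_hypnogram():
    return Hypnogram(stages=["N2"] * 20)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
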