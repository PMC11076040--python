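import numpy as np
import pytest
from hypothesis import settings

from collabhunt.env import ConditionConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def solo_fast():
    """One fast predator vs prey."""
    return ConditionConfig.from_names(1, "fast", "individual")


@pytest.fixture
def two_slow_shared():
    """Two slow predators with reward sharing (the collaboration cell)."""
    return ConditionConfig.from_names(2, "slow", "shared")


@pytest.fixture
def three_equal_shared():
    return ConditionConfig.from_names(3, "equal", "shared")
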