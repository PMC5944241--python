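import numpy as np
import pytest

from pepcharge import simulate as sim


@pytest.fixture
def arg8_scenario():
    return sim.default_scenario("ARG8", seed=42)


@pytest.fixture
def lys8_scenario():
    return sim.default_scenario("LYS8", seed=43)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
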