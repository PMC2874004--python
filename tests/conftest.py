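import warnings

import numpy as np
import pytest

from nestsim import SimConfig, make_micro_world


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """1 km^2 world with 2 orangutans: the fastest full-mechanism config."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_micro_world(grid_side=500, first_survey_day=300)


@pytest.fixture(scope="session")
def small_config():
    """4 km^2 world with 8 orangutans for statistics that need more nests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_micro_world(grid_side=1000, first_survey_day=800)
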