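import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from iicr import (
    SamplingScheme,
    add_population_split,
    make_n_island,
)


@pytest.fixture(scope="session")
def log_grid():
    return np.geomspace(1e-3, 1e2, 64)


@pytest.fixture(scope="session")
def same_deme():
    return SamplingScheme(0, 0)


@pytest.fixture(scope="session")
def diff_deme():
    return SamplingScheme(0, 1)


@pytest.fixture(scope="session")
def split_model_fig_two_island():
    """Two islands (M=1) merging at T=2 into one ancestral deme of size 2."""
    return add_population_split(make_n_island(2, 1), 2.0, [0, 1], ancestral_size=2.0)
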