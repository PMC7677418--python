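import numpy as np
import pytest

from moralsim import default_population_spec, default_vocabulary


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


@pytest.fixture(scope="session")
def av_gaussian_spec():
    return default_population_spec("av", "0")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
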