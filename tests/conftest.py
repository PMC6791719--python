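import numpy as np
import pytest

from nbclones import load_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def fitted_params(fixtures):
    return fixtures.fitted_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
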