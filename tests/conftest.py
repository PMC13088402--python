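import numpy as np
import pytest

from hvsi.bruitsim import simulate_cohort
from hvsi.io_cli import load_verification_fixture


@pytest.fixture(scope="session")
def verification20():
    return load_verification_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """200 + 200 surrogate cohort, fixed seed, reused across tests."""
    return simulate_cohort(200, 200, seed=123).records


@pytest.fixture()
def rng():
    return np.random.default_rng(20240301)
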