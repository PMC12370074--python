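import numpy as np
import pytest

from crocsurvey.synthetic import SyntheticConfig, simulate_survey


@pytest.fixture(scope="session")
def small_config():
    """A compact but otherwise default-structured synthetic survey."""
    return SyntheticConfig(n_cells=150, seed=42)


@pytest.fixture(scope="session")
def small_survey(small_config):
    return simulate_survey(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
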