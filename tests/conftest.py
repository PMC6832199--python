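import logging

import numpy as np
import pytest

from mirscore.synthetic import default_study_config, simulate_cohort

logging.getLogger("mirscore").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def default_config():
    return default_study_config(seed=20_19)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return simulate_cohort(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1644)
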