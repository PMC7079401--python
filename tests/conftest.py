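import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from stressproc.synth import analysis_frame, default_config, generate

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def cohort(config):
    """One default-sized synthetic cohort, shared across tests."""
    return generate(config, seed=20_260)


@pytest.fixture(scope="session")
def frame(cohort):
    """The SEM analysis variables derived from the shared cohort."""
    return analysis_frame(cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(915)
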