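import numpy as np
import pytest
from hypothesis import settings

import housenet as hn

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_spec():
    return hn.default_precision_spec()


@pytest.fixture(scope="session")
def marginals():
    return hn.default_marginals()


@pytest.fixture(scope="session")
def clean_cohort(planted_spec, marginals):
    """Complete cohort at the study's analyzed size, no missingness or selection."""
    return hn.simulate_cohort(planted_spec, marginals, 9669, seed=2024)


@pytest.fixture(scope="session")
def small_cohort(planted_spec, marginals):
    return hn.simulate_cohort(planted_spec, marginals, 800, seed=7)
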