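import numpy as np
import pytest

import tbsdc


@pytest.fixture(scope="session")
def uganda_prev():
    return tbsdc.load_scenario(None, "Uganda", "prevalence")


@pytest.fixture(scope="session")
def kenya_inc():
    return tbsdc.load_scenario(None, "Kenya", "incidence")


@pytest.fixture(scope="session")
def kenya_prev():
    return tbsdc.load_scenario(None, "Kenya", "prevalence")


@pytest.fixture(scope="session")
def ethiopia_prev():
    return tbsdc.load_scenario(None, "Ethiopia", "prevalence")


@pytest.fixture(scope="session")
def published():
    df = tbsdc.load_published_estimates()
    return df.set_index(["country", "scenario"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
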