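import numpy as np
import pytest

from prehabsim.synthetic_cohort import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()

@pytest.fixture(scope="session")
def default_cohort(default_config):
    """One reference cohort (n = 71) under the default calibration."""
    return generate_cohort(default_config, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
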