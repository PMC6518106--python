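import numpy as np
import pytest
from hypothesis import settings

from iaqsim.building import default_apartment
from iaqsim.scenarios import RunConfig
from iaqsim.synth_env import generate_aer, generate_ambient

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def env_seed1():
    """One shared environment realization (ambient PM2.5 + AER), seed 1."""
    cfg = RunConfig(seed=1)
    return generate_ambient(cfg.resolved_ambient_params()), generate_aer(
        cfg.resolved_aer_params()
    )


@pytest.fixture()
def apartment():
    return default_apartment()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
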