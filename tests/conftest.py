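import numpy as np
import pytest
from hypothesis import settings

from tslecc import ScenarioConfig, default_release_model, simulate_scenario

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def release_model():
    return default_release_model()


@pytest.fixture(scope="session")
def scenario():
    """Reference scenario: in vivo subject/dose/circuit with calibrated rates."""
    return ScenarioConfig()


@pytest.fixture(scope="session")
def ecc_trajectory(scenario):
    """Reference filtration run: constant 55% efficacy, 60 min from t=30."""
    return simulate_scenario(scenario.with_constant_efficacy(0.55))


@pytest.fixture(scope="session")
def noecc_trajectory(scenario):
    return simulate_scenario(scenario.without_ecc())


@pytest.fixture()
def rng():
    return np.random.default_rng(20220304)
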