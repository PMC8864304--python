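import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from csmf519.synth import ScenarioConfig, make_truth, simulate_scenario
from csmf519.taxonomy import AgeSexGroup, default_taxonomy

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tax59():
    return default_taxonomy(AgeSexGroup.AGE_5_9)


@pytest.fixture(scope="session")
def tax1014():
    return default_taxonomy(AgeSexGroup.AGE_10_14)


SMALL_CONFIG = ScenarioConfig(
    n_countries=12,
    n_hqvr=2,
    n_lmm=4,
    n_study_countries=6,
    groups=(AgeSexGroup.AGE_5_9,),
    n_envelope_draws=50,
)


@pytest.fixture(scope="session")
def small_truth():
    return make_truth(seed=11, config=SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_scenario(11, SMALL_CONFIG)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_simplex(rng: np.random.Generator, n: int) -> np.ndarray:
    x = rng.dirichlet(np.ones(n))
    return x
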