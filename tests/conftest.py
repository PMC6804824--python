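import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import scentvar as sv

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_config() -> sv.SimulationConfig:
    return sv.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def sim(sim_config):
    """One full synthetic study (locus, haplotype panel, emissions)."""
    return sv.simulate_all(sim_config)


@pytest.fixture(scope="session")
def locus(sim):
    return sim[0]


@pytest.fixture(scope="session")
def panel(sim):
    return sim[1]


@pytest.fixture(scope="session")
def emissions(sim):
    return sim[2]


@pytest.fixture(scope="session")
def ref_orf(locus):
    return sv.find_orf(locus.cdnas["canonical"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
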