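import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from smartbias import SimConfig, make_genome

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    """Default study conditions on a compact genome for module tests."""
    return SimConfig(genome_length=300_000, n_fragments=20_000)


@pytest.fixture(scope="session")
def genome_and_truth(sim_config):
    return make_genome(sim_config, seed=11)


@pytest.fixture(scope="session")
def genome(genome_and_truth):
    return genome_and_truth[0]


@pytest.fixture(scope="session")
def truth_tracts(genome_and_truth):
    return genome_and_truth[1]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_sequence(rng: np.random.Generator, n: int, p=None) -> str:
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
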