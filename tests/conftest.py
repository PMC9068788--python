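import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from methyltf import SimConfig, simulate_study

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: 100 kb genome, 8 planted sites, 40 probes."""
    return SimConfig(
        genome_length=100_000, n_probes=40, n_planted_sites=8,
        noise_sd=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def default_study():
    return simulate_study(SimConfig(seed=11))


@pytest.fixture
def toy_mvalues():
    return pd.DataFrame(
        {
            "t0": [1.0, 1.0, 0.0, 3.0],
            "t1": [3.5, -1.5, 2.0, 3.1],
            "t2": [3.6, -1.6, 2.1, -0.5],
        },
        index=["pA", "pB", "pC", "pD"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
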