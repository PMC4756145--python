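import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_sim_config():
    """Small cohort for fast unit tests: 6 subjects, 120 volumes, 4 networks."""
    from ifcpipe import SimConfig

    return SimConfig(n_per_group=3, n_volumes=120, n_latent_networks=4, seed=11)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_sim_config):
    from ifcpipe import generate_cohort

    return generate_cohort(tiny_sim_config)


@pytest.fixture(scope="session")
def tiny_run_config():
    """End-to-end config small enough for repeated pipeline runs."""
    from ifcpipe import IcaConfig, RunConfig, SimConfig

    return RunConfig(
        sim=SimConfig(n_per_group=4, n_volumes=150, n_latent_networks=4),
        ica=IcaConfig(n_group_components=4, n_icasso_runs=4),
        seed=23,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
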