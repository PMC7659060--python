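import pytest

from famsurvey.synthetic_data import SimConfig, simulate_family


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def bundle(sim_config):
    """Default synthetic bundle shared across tests (read-only)."""
    return simulate_family(sim_config)
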