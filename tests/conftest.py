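import pytest
from hypothesis import settings

import ruralfv as rf

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rural_config():
    return rf.rural_tx()


@pytest.fixture(scope="session")
def small_config(rural_config):
    """Desk-scale rural community (~516 agents) for fast unit tests."""
    return rural_config.replace(subsample_factor=0.1)


@pytest.fixture(scope="session")
def small_community(small_config):
    return rf.build_community(small_config, seed=7)


@pytest.fixture(scope="session")
def rural_community(rural_config):
    """Full-scale rural community (5,157 agents)."""
    return rf.build_community(rural_config, seed=7)


@pytest.fixture()
def params():
    return rf.BehaviorParams()


@pytest.fixture()
def fast_spec():
    return rf.SimulationSpec(n_days=16, burn_in_days=4, n_replicates=3, base_seed=11)
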