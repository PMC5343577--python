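import pytest
from hypothesis import HealthCheck, settings

from mitocomp.fixtures import episyrphus_genome, eupeodes_genome
from mitocomp.simulate import SimulationConfig, simulate_genome, evolve_on_tree

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def episyrphus():
    return episyrphus_genome()


@pytest.fixture(scope="session")
def eupeodes():
    return eupeodes_genome()


@pytest.fixture(scope="session")
def sim_genome():
    return simulate_genome(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def sim_panel(sim_genome):
    return evolve_on_tree(sim_genome, SimulationConfig(seed=1))
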