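import pytest

from polterm.simulate import SimulationScenario, simulate_genome


@pytest.fixture
def scenario():
    """Default study conditions, scaled to 20 genes for unit-test speed."""
    return SimulationScenario(seed=7, n_genes=20)


@pytest.fixture
def noise_free(scenario):
    return scenario.with_overrides(noise_model="none")


@pytest.fixture
def genome(noise_free):
    return simulate_genome(noise_free)
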