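import pytest

import ricewue as rw


@pytest.fixture(scope="session")
def registry():
    return rw.default_registry()


@pytest.fixture(scope="session")
def sim_dataset():
    """One default synthetic experiment (21 genotypes, 2 trials, 8 reps)."""
    return rw.generate_dataset(rw.SimulationConfig(seed=1))


@pytest.fixture
def table(sim_dataset):
    return sim_dataset[0]


@pytest.fixture
def truth(sim_dataset):
    return sim_dataset[1]
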