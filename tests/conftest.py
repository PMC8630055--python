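import numpy as np
import pytest

from wmlearn import PopulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """Six participants, fixed seed — enough for fast fitting checks."""
    return simulate_dataset(PopulationConfig(n_participants=6, seed=11))


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort (87 participants) at the default population."""
    return simulate_dataset(PopulationConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
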