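import numpy as np
import pytest

from dfnc import ScenarioConfig, simulate_cohort


@pytest.fixture(scope="session")
def tiny_scenario() -> ScenarioConfig:
    """A fast three-state scenario for structural tests."""
    return ScenarioConfig(
        n_states=3, n_subjects_per_group=(4, 3), n_timepoints=120, seed=11
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_scenario):
    return simulate_cohort(tiny_scenario)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
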