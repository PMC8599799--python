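import numpy as np
import pytest

from footprintr import SimulationParams, simulate_experiment
from footprintr.reactivity import Condition


SMALL = dict(
    n_transcripts=20,
    length_min=500,
    length_max=600,
    coverage=150.0,
    seed=11,
)


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    return SimulationParams(**SMALL)


@pytest.fixture(scope="session")
def small_experiment(small_params):
    """A modest synthetic experiment shared by read-only tests."""
    return simulate_experiment(small_params)


@pytest.fixture(scope="session")
def small_in_cell_experiment(small_params):
    return simulate_experiment(small_params, conditions=(Condition.IN_CELL,))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
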