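import numpy as np
import pytest

from rdex.design import build_map
from rdex.simulate import BASE_TRUTH, make_schedule, simulate_dataset, trials_from_table


@pytest.fixture(scope="session")
def pmap():
    return build_map()


@pytest.fixture(scope="session")
def base_truth(pmap):
    return BASE_TRUTH(pmap)


@pytest.fixture(scope="session")
def small_dataset(pmap, base_truth):
    """One simulated participant (960 trials, staircase SSD)."""
    schedule = make_schedule(seed=11)
    return simulate_dataset(schedule, base_truth, pmap, seed=12)


@pytest.fixture(scope="session")
def small_trials(small_dataset):
    return trials_from_table(small_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
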