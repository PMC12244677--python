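import numpy as np
import pytest

from armloop import datasets
from armloop.fixtures import FixtureSpec, generate_fixture
from armloop.loop import system_gain_margin
from armloop.tables import FeedbackParams


@pytest.fixture(scope="session")
def gain_matrix():
    return datasets.spindle_gain_matrix()


@pytest.fixture(scope="session")
def ecd():
    return datasets.excess_central_delay()


@pytest.fixture(scope="session")
def delay_tables():
    return datasets.solved_delays()


@pytest.fixture(scope="session")
def muscle_table():
    return datasets.muscle_parameters()


@pytest.fixture(scope="session")
def plant_params():
    return generate_fixture(FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def feedback(gain_matrix):
    return FeedbackParams(G=gain_matrix, c=0.0)


@pytest.fixture(scope="session")
def margin(plant_params, feedback, delay_tables):
    return system_gain_margin(plant_params, feedback, delay_tables)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
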