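import numpy as np
import pytest

from doseinsert import DesignConfig, TrialState, load_scenario, pipe_prior


@pytest.fixture
def prior_state():
    """Fresh 3x3 trial state with the operational PIPE prior."""
    means, ss, _ = pipe_prior((3, 3))
    return TrialState.from_prior(means, ss)


@pytest.fixture
def config():
    return DesignConfig()


@pytest.fixture
def scenario_a1():
    return load_scenario("A1")


def random_monotone_matrix(rng, shape=(3, 3), lo=0.0, hi=1.0):
    """Random monotone nondecreasing matrix via cumulative sums."""
    increments = rng.random(shape)
    m = increments.cumsum(axis=0).cumsum(axis=1)
    m = m / m[-1, -1]
    return lo + (hi - lo) * m
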