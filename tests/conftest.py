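import numpy as np
import pytest

from langcoevo.core import (
    Agent,
    AgentPopulation,
    LanguagePopulation,
    SimParams,
    run_communication_round,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_params():
    return SimParams(N=4, generations=1, init_num_languages=1, seed=7)


def make_log(agents, langs, seed=0):
    """Communication log for hand-built populations."""
    pop = AgentPopulation.from_agents(agents)
    return run_communication_round(pop, langs, np.random.default_rng(seed))


def lang_pop(*positions):
    return LanguagePopulation.from_positions(list(positions))


@pytest.fixture
def small_trace():
    """A short but eventful default-parameter run at toy scale."""
    from langcoevo.core import run_simulation

    params = SimParams(N=40, generations=120, init_num_languages=20, seed=11)
    return run_simulation(params)
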