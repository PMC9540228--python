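import numpy as np
import pytest
from hypothesis import settings

from birdwatch import agents, analysis
from birdwatch.engine import EngineConfig

settings.register_profile("ci", derandomize=True, max_examples=60,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> EngineConfig:
    return EngineConfig()


@pytest.fixture(scope="session")
def sim_participant(config):
    """One deterministic simulated participant (block log, survey log)."""
    agent = agents.AgentParams()
    return agents.simulate_participant(agent, config, seed=20240101,
                                       participant_id="p001")


@pytest.fixture(scope="session")
def sim_scored(sim_participant):
    blocks, _ = sim_participant
    return analysis.score_blocks(blocks)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(987654321)
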