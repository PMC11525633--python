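import numpy as np
import pytest

from intentnav import AgentModel, NetworkConfig, TMazeEnv
from intentnav.fixtures import tiny_maze_config


@pytest.fixture(scope="session")
def tiny_model():
    return AgentModel(NetworkConfig.tiny(), seed=0)


@pytest.fixture(scope="session")
def micro_model():
    return AgentModel(NetworkConfig.micro(), seed=0)


@pytest.fixture()
def tiny_env():
    return TMazeEnv(tiny_maze_config())


@pytest.fixture()
def default_env():
    from intentnav import MazeConfig

    return TMazeEnv(MazeConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
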