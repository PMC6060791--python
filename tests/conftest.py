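import numpy as np
import pytest

from mazenav.environment import generate_maze
from mazenav.experiments import run_exploration
from mazenav.model_core import AgentConfig, MazeGrid


@pytest.fixture(scope="session")
def maze8():
    return generate_maze(seed=3)


@pytest.fixture(scope="session")
def exploration(maze8):
    """One full 32-trial exploration session with a recorded trace."""
    return run_exploration(maze8, n_trials=32)


@pytest.fixture()
def corridor5():
    cells = np.zeros((1, 5), dtype=np.int8)
    return MazeGrid(cells=cells, start=0, target=4)


@pytest.fixture()
def open_grid8():
    cells = np.zeros((8, 8), dtype=np.int8)
    return MazeGrid(cells=cells, start=56, target=20)


@pytest.fixture()
def config():
    return AgentConfig()
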