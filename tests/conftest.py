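import warnings

import pytest
from hypothesis import HealthCheck, settings

from tcgsim.gridworld import BoardSpec, GoalConfiguration, generate_configurations

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# parameter-band advisories are expected in sweeps that probe wide ranges
warnings.filterwarnings("ignore", message=".*outside the usual.*")


@pytest.fixture(scope="session")
def board():
    return BoardSpec(3, 3)


@pytest.fixture(scope="session")
def all_configs(board):
    """Every distinct-triple goal configuration on the 3x3 board (504)."""
    cells = list(board.cells())
    return [
        GoalConfiguration(A=a, Gs=gs, Gr=gr, board=board)
        for a in cells
        for gs in cells
        for gr in cells
        if len({a, gs, gr}) == 3
    ]


@pytest.fixture(scope="session")
def study_configs(board):
    """The session design: 20 direct + 10 indirect trials, fixed seed."""
    return generate_configurations(board, 20, 10, seed=0)
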