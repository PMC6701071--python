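import pytest

from smokesim import (
    BehaviorParams,
    InitialConditions,
    TimeGrid,
    generate_env_inputs,
    simulate,
)


@pytest.fixture(scope="session")
def params():
    return BehaviorParams()


@pytest.fixture(scope="session")
def env():
    return generate_env_inputs()


@pytest.fixture(scope="session")
def init():
    return InitialConditions()


@pytest.fixture(scope="session")
def grid():
    return TimeGrid()


@pytest.fixture(scope="session")
def coarse_grid():
    # quarter-year steps: ~4x faster, well inside the convergence envelope
    return TimeGrid(dt=0.25)


@pytest.fixture(scope="session")
def base_traj(params, env, init, grid):
    """The default 1992-2032 base run, shared across tests."""
    return simulate(params, env, init, grid)
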