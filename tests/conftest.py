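import numpy as np
import pytest

from acidinvasion import (
    DimensionlessParams,
    Grid1D,
    InitialConditionSpec,
    SolverSettings,
    build_initial_state,
    integrate,
)


@pytest.fixture(scope="session")
def defaults() -> DimensionlessParams:
    return DimensionlessParams()


@pytest.fixture(scope="session")
def grid() -> Grid1D:
    return Grid1D()


@pytest.fixture(scope="session")
def coarse_grid() -> Grid1D:
    return Grid1D(n_points=60)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20231206)


@pytest.fixture(scope="session")
def coexistence_trajectory(defaults, grid):
    """Default (c_MA, c_AM) = (0, 0) run to t=50 at reference tolerance."""
    state0 = build_initial_state(grid, InitialConditionSpec())
    settings = SolverSettings(snapshot_times=(0.0, 25.0, 50.0))
    return integrate(state0, defaults, grid, settings)


@pytest.fixture(scope="session")
def quick_trajectory(defaults, coarse_grid):
    """Short, coarse coexistence run for cheap property checks."""
    state0 = build_initial_state(coarse_grid, InitialConditionSpec())
    settings = SolverSettings(
        rel_tol=1e-8, abs_tol=1e-8, snapshot_times=(0.0, 1.0, 2.0, 5.0, 10.0)
    )
    return integrate(state0, defaults, coarse_grid, settings)
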