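import numpy as np
import pytest

from cogmap.cells import EnsembleParams
from cogmap.pipeline import SessionConfig, simulate_session


@pytest.fixture(scope="session")
def small_config() -> SessionConfig:
    """A five-minute, 60-cell session: big enough to have nontrivial
    topology, small enough to run in about a second."""
    return SessionConfig(duration=300.0, ensemble=EnsembleParams(N=60))


@pytest.fixture(scope="session")
def small_session(small_config):
    return simulate_session(small_config, seed=11)


@pytest.fixture(scope="session")
def hour_trajectory():
    """One-hour exploratory trajectory in the default arena (shared across
    occupancy/coverage tests)."""
    from cogmap.arena import make_arena, simulate_trajectory

    arena = make_arena(100.0, 100.0, 20.0)
    return arena, simulate_trajectory(arena, duration=3600.0, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
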