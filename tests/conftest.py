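import numpy as np
import pytest

from defensim import GridState, SimulationParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def base_params():
    """Small, fast parameter set with the standard rate constants."""
    return SimulationParams(M=20, n_B0=20, max_generations=2000, f=0.0)


def half_and_half(M: int) -> GridState:
    """Full lattice, producers on the left half, parasites on the right."""
    state = GridState.empty(M)
    state.occupancy[:, : M // 2] = 1
    state.occupancy[:, M // 2:] = 2
    return state
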