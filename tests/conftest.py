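import numpy as np
import pytest

from tugwar import ModelParams, OriginKind, PopulationState


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def build_state(N, clones):
    """Population from a list of (parent_id, alpha, beta, origin, fitness, live)."""
    state = PopulationState(N)
    for parent, alpha, beta, origin, fitness, live in clones:
        state.add_clone(parent, alpha, beta, OriginKind(origin), fitness, live)
    return state


@pytest.fixture
def chain_state():
    """root -> c1 -> c2 with live cells (0, 2, 3), N = 5."""
    return build_state(
        5,
        [
            (None, 0, 0, "root", 1.0, 0),
            (0, 0, 1, "passenger", 0.9, 2),
            (1, 0, 2, "passenger", 0.81, 3),
        ],
    )


@pytest.fixture
def star_state():
    """root with two children of 2 and 3 cells, N = 5."""
    return build_state(
        5,
        [
            (None, 0, 0, "root", 1.0, 0),
            (0, 1, 0, "driver", 1.5, 2),
            (0, 0, 1, "passenger", 0.9, 3),
        ],
    )


def brute_force_carriers(state):
    """Carrier counts by explicit per-cell mutation sets (independent oracle).

    Enumerates every live cell, walks its clone's root path to list the
    mutations (non-root clone ids) it carries, and tallies carriers per
    mutation.
    """
    counts = {
        i: 0 for i in range(state.n_clones) if state.parent[i] >= 0
    }
    for i in range(state.n_clones):
        path = []
        j = i
        while j >= 0:
            if state.parent[j] >= 0:
                path.append(j)
            j = int(state.parent[j])
        for _ in range(int(state.live[i])):
            for m in path:
                counts[m] += 1
    return counts
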