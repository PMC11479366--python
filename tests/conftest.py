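"""Shared fixtures: canonical layout, converged-agent weights, full-scale grid.

The full-scale grid (25 configurations x 100 runs x 100 episodes) is
expensive (~1 minute), so it is simulated once per session and shared by
the statistical reproduction tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from tmaze_pf import (
    AgentWeights,
    adaptation_frame,
    build_layout,
    build_tables,
    run_grid,
    runs_frame,
)

ACCEPTANCE_BASE_SEED = 20240925


@pytest.fixture(scope="session")
def layout():
    return build_layout()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def converged_weights(layout, goal_cell) -> AgentWeights:
    """Analytic post-learning weights: state values decay as gamma**distance.

    Encodes the converged successor representation of the goal-directed
    policy just enough for greedy action selection: with wr the one-hot of
    the goal and W's goal row holding gamma**BFS-distance per cell, the
    one-step-lookahead value of any cell is gamma**distance, so greedy
    descent follows a shortest path.
    """
    gamma = 0.95
    d = layout.d
    W = np.zeros((d, d))
    goal_feat = layout.feature_index(goal_cell)
    for cell in layout.corridor:
        dist = layout.shortest_path_length(cell, goal_cell)
        W[goal_feat, layout.feature_index(cell)] = gamma**dist
    wr = np.zeros(d)
    wr[goal_feat] = 1.0
    return AgentWeights(W=W, wr=wr, e=np.zeros(d))


@pytest.fixture(scope="session")
def full_grid_results():
    """The full-scale study: 5x5 grid, 100 seeded runs of 100 episodes."""
    return run_grid(n_runs=100, base_seed=ACCEPTANCE_BASE_SEED)


@pytest.fixture(scope="session")
def full_grid_tables(full_grid_results):
    runs = runs_frame(full_grid_results)
    adaptation = adaptation_frame(full_grid_results)
    return runs, adaptation, build_tables(runs, adaptation)
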