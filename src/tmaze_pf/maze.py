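"""T-maze gridworld: layout, deterministic dynamics, goal schedule, noisy observations.

The environment is a T-shaped corridor embedded in a 9x9 grid: a vertical
stem from the bottom-centre start cell up to a junction, and a horizontal
bar whose two ends hold the candidate reward sites.  Transitions are
deterministic (a move into a wall leaves the agent in place); the only
stochasticity the agent ever sees is i.i.d. Gaussian noise added to the
one-hot state feature vector at observation time.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

Cell = tuple[int, int]

#: Action names in canonical order; the integer encoding used throughout
#: (and inside the compiled run loop) is the index into this tuple.
ACTIONS: tuple[str, ...] = ("up", "down", "left", "right")

_DELTAS: dict[str, Cell] = {
    "up": (-1, 0),
    "down": (1, 0),
    "left": (0, -1),
    "right": (0, 1),
}

GOAL_SIDES: tuple[str, str] = ("left", "right")


@dataclass(frozen=True)
class MazeLayout:
    """Immutable description of the maze graph and its feature embedding.

    ``state_index`` is a bijection from corridor cells to ``0..n-1`` (row-major
    order).  The observation dimension ``d`` equals the number of corridor
    cells when ``feature_space='corridor'`` (default) or the full grid size
    when ``feature_space='full'``; in both cases each corridor cell maps to a
    distinct one-hot coordinate via ``feature_index``.
    """

    grid_height: int
    grid_width: int
    corridor: tuple[Cell, ...]
    start: Cell
    goal_left: Cell
    goal_right: Cell
    junction: Cell
    feature_space: str = "corridor"
    state_index: dict[Cell, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        cells = tuple(sorted(self.corridor))
        object.__setattr__(self, "corridor", cells)
        object.__setattr__(self, "state_index", {c: i for i, c in enumerate(cells)})
        _validate_layout(self)

    @property
    def n_states(self) -> int:
        return len(self.corridor)

    @property
    def d(self) -> int:
        if self.feature_space == "full":
            return self.grid_height * self.grid_width
        return len(self.corridor)

    def feature_index(self, cell: Cell) -> int:
        """One-hot coordinate of a corridor cell."""
        if self.feature_space == "full":
            return cell[0] * self.grid_width + cell[1]
        return self.state_index[cell]

    def one_hot(self, cell: Cell) -> np.ndarray:
        phi = np.zeros(self.d)
        phi[self.feature_index(cell)] = 1.0
        return phi

    def goal_cell(self, side: str) -> Cell:
        if side == "left":
            return self.goal_left
        if side == "right":
            return self.goal_right
        raise ValueError(f"unknown goal side {side!r}")

    def successor(self, cell: Cell, action: str) -> Cell:
        """Deterministic next cell; moves into walls are identity."""
        dr, dc = _DELTAS[action]
        cand = (cell[0] + dr, cell[1] + dc)
        return cand if cand in self.state_index else cell

    def successor_table(self) -> np.ndarray:
        """(n_states, 4) int array: successor state index per state and action."""
        table = np.empty((self.n_states, len(ACTIONS)), dtype=np.int64)
        for cell, i in self.state_index.items():
            for a, name in enumerate(ACTIONS):
                table[i, a] = self.state_index[self.successor(cell, name)]
        return table

    def feature_table(self) -> np.ndarray:
        """(n_states,) int array mapping state index -> one-hot coordinate."""
        return np.array(
            [self.feature_index(c) for c in self.corridor], dtype=np.int64
        )

    def shortest_path_length(self, a: Cell, b: Cell) -> int:
        """BFS distance between two corridor cells under 4-neighbour moves."""
        if a not in self.state_index or b not in self.state_index:
            raise ValueError("cells must lie on the corridor")
        dist = {a: 0}
        queue = deque([a])
        while queue:
            cell = queue.popleft()
            if cell == b:
                return dist[cell]
            for name in ACTIONS:
                nxt = self.successor(cell, name)
                if nxt not in dist:
                    dist[nxt] = dist[cell] + 1
                    queue.append(nxt)
        raise ValueError(f"no corridor path from {a} to {b}")


def _validate_layout(layout: MazeLayout) -> None:
    if layout.feature_space not in ("corridor", "full"):
        raise ValueError(f"unknown feature_space {layout.feature_space!r}")
    if not layout.corridor:
        raise ValueError("corridor is empty")
    for r, c in layout.corridor:
        if not (0 <= r < layout.grid_height and 0 <= c < layout.grid_width):
            raise ValueError(f"corridor cell {(r, c)} outside the grid")
    for name, cell in (
        ("start", layout.start),
        ("goal_left", layout.goal_left),
        ("goal_right", layout.goal_right),
        ("junction", layout.junction),
    ):
        if cell not in layout.state_index:
            raise ValueError(f"{name} cell {cell} is not on the corridor")
    # connectivity: BFS from start must reach every corridor cell
    seen = {layout.start}
    queue = deque([layout.start])
    while queue:
        cell = queue.popleft()
        for name in ACTIONS:
            nxt = layout.successor(cell, name)
            if nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)
    if len(seen) != len(layout.corridor):
        missing = sorted(set(layout.corridor) - seen)
        raise ValueError(f"corridor is disconnected; unreachable cells: {missing}")


def build_layout(
    corridor: Iterable[Cell] | None = None,
    *,
    grid_height: int = 9,
    grid_width: int = 9,
    start: Cell = (8, 4),
    goal_left: Cell = (0, 0),
    goal_right: Cell = (0, 8),
    junction: Cell = (0, 4),
    feature_space: str = "corridor",
) -> MazeLayout:
    """Build the canonical 9x9 T-maze, or a custom corridor for testing.

    The canonical corridor is the vertical stem (column 4, rows 1-8) plus the
    full top row (row 0, columns 0-8): 17 cells, with the start at the bottom
    of the stem and the goals at the two ends of the bar.  The shortest path
    from start to either goal is 12 steps (8 up the stem + 4 along the bar).
    """
    if corridor is None:
        stem = [(r, 4) for r in range(1, grid_height)]
        bar = [(0, c) for c in range(grid_width)]
        corridor = stem + bar
    return MazeLayout(
        grid_height=grid_height,
        grid_width=grid_width,
        corridor=tuple(corridor),
        start=start,
        goal_left=goal_left,
        goal_right=goal_right,
        junction=junction,
        feature_space=feature_space,
    )


def goal_schedule(episode_index: int, initial_side: str = "left", period: int = 20) -> str:
    """Active goal arm for an episode: alternates sides every ``period`` episodes."""
    if episode_index < 0:
        raise ValueError("episode_index must be non-negative")
    if period < 1:
        raise ValueError("period must be >= 1")
    if initial_side not in GOAL_SIDES:
        raise ValueError(f"unknown side {initial_side!r}")
    if (episode_index // period) % 2 == 0:
        return initial_side
    return "right" if initial_side == "left" else "left"


@dataclass
class EnvState:
    """Mutable-looking but treated as a value: one agent position within an episode."""

    position: Cell
    goal_side: str
    step_count: int = 0
    episode_index: int = 0
    done: bool = False


def reset_env(layout: MazeLayout, episode_index: int, goal_side: str) -> EnvState:
    """Fresh episode state at the start cell."""
    return EnvState(
        position=layout.start,
        goal_side=goal_side,
        step_count=0,
        episode_index=episode_index,
        done=False,
    )


def env_step(
    state: EnvState,
    action: str,
    layout: MazeLayout,
    max_steps: int = 500,
) -> tuple[EnvState, float, bool]:
    """One deterministic transition; returns ``(new_state, reward, done)``.

    A move into a wall leaves the position unchanged and does not consume
    any of the episode's step budget: the step counter counts actual
    movements, so the 500-step cap bounds the path length rather than the
    number of attempted actions.  (The agent still observes and learns from
    a blocked attempt as a self-transition.)  Reaching the active goal
    yields reward 1 and ends the episode; the goal test precedes the
    step-cap test, so a goal reached exactly on the capped step still
    counts.  Hitting the cap without the goal ends with reward 0.
    """
    if state.done:
        raise ValueError("cannot step a finished episode")
    if action not in _DELTAS:
        raise ValueError(f"unknown action {action!r}")
    pos = layout.successor(state.position, action)
    blocked = pos == state.position
    steps = state.step_count if blocked else state.step_count + 1
    goal = layout.goal_cell(state.goal_side)
    if not blocked and pos == goal:
        reward, done = 1.0, True
    elif not blocked and steps >= max_steps:
        reward, done = 0.0, True
    else:
        reward, done = 0.0, False
    new_state = replace(state, position=pos, step_count=steps, done=done)
    return new_state, reward, done


def observe(
    state: EnvState,
    sigma: float,
    rng: np.random.Generator,
    layout: MazeLayout,
) -> np.ndarray:
    """Noisy observation o = phi(s) + eps with eps ~ N(0, sigma^2 I).

    Exactly one observation is drawn per time step; the caller reuses the
    post-transition observation as the pre-transition observation of the
    next step.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    phi = layout.one_hot(state.position)
    if sigma > 0:
        phi += sigma * rng.standard_normal(layout.d)
    return phi
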