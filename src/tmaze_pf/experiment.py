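"""Experiment orchestration: episodes -> trials -> the hyperparameter grid.

A *trial* (one run) is a sequence of episodes in which the agent's weights
persist -- the goal relocations inside a trial are the transfer events under
study; only the eligibility trace and the environment reset between
episodes.  A *grid* crosses the swept hyperparameters (trace decay lambda,
reward learning rate alpha_r) and repeats each configuration over seeded
independent runs.

Two engines produce bit-identical results: a pure-Python reference built
from the :mod:`tmaze_pf.maze` / :mod:`tmaze_pf.agent` primitives, and a
compiled fast path (:mod:`tmaze_pf._kernel`) used by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .agent import (
    AgentParams,
    AgentWeights,
    epsilon,
    init_weights,
    q_values,
    select_action,
    td_update,
)
from .maze import (
    GOAL_SIDES,
    EnvState,
    MazeLayout,
    build_layout,
    env_step,
    goal_schedule,
    observe,
    reset_env,
)

logger = logging.getLogger(__name__)

#: Hyperparameter grids of the study: 5 trace decays x 5 reward learning rates.
DEFAULT_LAMS: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8)
DEFAULT_ALPHA_RS: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass(frozen=True)
class EpisodeResult:
    episode_index: int
    steps: int
    reward: int
    goal_side: str


@dataclass
class RunResult:
    """Complete log of one run: hyperparameters, seed, per-episode outcomes."""

    lam: float
    alpha_r: float
    run_id: int
    seed: int
    episodes: list[EpisodeResult] = field(default_factory=list)

    @property
    def rewards(self) -> np.ndarray:
        return np.array([ep.reward for ep in self.episodes], dtype=np.int64)

    @property
    def steps(self) -> np.ndarray:
        return np.array([ep.steps for ep in self.episodes], dtype=np.int64)

    @property
    def n_episodes(self) -> int:
        return len(self.episodes)


def run_seed(base_seed: int, lam: float, alpha_r: float, run_id: int) -> int:
    """Stable per-run seed derived from the base seed and configuration.

    Uses a seed sequence keyed on the configuration so any subset of the grid
    is reproducible independently of which other configurations are run.
    """
    entropy = [
        int(base_seed),
        int(round(lam * 10**6)),
        int(round(alpha_r * 10**6)),
        int(run_id),
    ]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0]) % 2**31


def run_episode(
    state: EnvState,
    weights: AgentWeights,
    params: AgentParams,
    layout: MazeLayout,
    rng: np.random.Generator,
) -> tuple[EpisodeResult, AgentWeights]:
    """Run one episode to termination, learning at every transition.

    The eligibility trace is reset at episode start; one observation is
    drawn per time step, each transition's arrival observation becoming the
    departure observation of the next.  Every attempted action is learned
    from, including blocked moves (a self-transition) and the terminal
    transition, whose bootstrap term is cut.
    """
    weights.e[:] = 0.0
    eps = epsilon(state.episode_index, params)
    o_t = observe(state, params.sigma, rng, layout)
    r = 0.0
    while not state.done:
        q = q_values(weights, state, layout)
        action = select_action(q, eps, rng)
        state, r, done = env_step(state, action, layout, params.max_steps)
        o_t1 = observe(state, params.sigma, rng, layout)
        td_update(weights, o_t, o_t1, r, params, terminal=done)
        o_t = o_t1
    result = EpisodeResult(
        episode_index=state.episode_index,
        steps=state.step_count,
        reward=int(r),
        goal_side=state.goal_side,
    )
    return result, weights


def run_trial(
    params: AgentParams,
    layout: MazeLayout | None = None,
    n_episodes: int = 100,
    switch_period: int = 20,
    initial_side: str = "left",
    run_id: int = 0,
    engine: str = "numba",
) -> RunResult:
    """Run one seeded trial of ``n_episodes`` episodes with persistent weights.

    A single generator seeded with ``params.seed`` drives, in fixed order,
    the weight initialisation and then each step's observation noise and
    policy draws, so trials are exactly reproducible.  The exploration
    schedule decays monotonically over the whole trial; it does not reset
    at goal relocations.
    """
    if n_episodes < 1:
        raise ValueError("n_episodes must be >= 1")
    if layout is None:
        layout = build_layout()
    rng = np.random.default_rng(params.seed)
    weights = init_weights(layout.d, rng)
    goal_sides = [
        goal_schedule(k, initial_side, switch_period) for k in range(n_episodes)
    ]

    if engine == "numba":
        from ._kernel import run_trial_kernel

        goal_states = np.array(
            [layout.state_index[layout.goal_cell(side)] for side in GOAL_SIDES],
            dtype=np.int64,
        )
        goal_side_idx = np.array(
            [GOAL_SIDES.index(side) for side in goal_sides], dtype=np.int64
        )
        eps_by_episode = np.array(
            [epsilon(k, params) for k in range(n_episodes)]
        )
        steps, rewards = run_trial_kernel(
            weights.W,
            weights.wr,
            layout.successor_table(),
            layout.feature_table(),
            np.int64(layout.state_index[layout.start]),
            goal_states,
            goal_side_idx,
            eps_by_episode,
            params.sigma,
            params.gamma,
            params.lam,
            params.alpha_W,
            params.alpha_r,
            np.int64(params.max_steps),
            rng,
        )
        episodes = [
            EpisodeResult(k, int(steps[k]), int(rewards[k]), goal_sides[k])
            for k in range(n_episodes)
        ]
    elif engine == "python":
        episodes = []
        for k in range(n_episodes):
            state = reset_env(layout, k, goal_sides[k])
            ep, weights = run_episode(state, weights, params, layout, rng)
            episodes.append(ep)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    return RunResult(
        lam=params.lam,
        alpha_r=params.alpha_r,
        run_id=run_id,
        seed=params.seed,
        episodes=episodes,
    )


def run_grid(
    lams: Sequence[float] = DEFAULT_LAMS,
    alpha_rs: Sequence[float] = DEFAULT_ALPHA_RS,
    n_runs: int = 100,
    base_seed: int = 0,
    layout: MazeLayout | None = None,
    n_episodes: int = 100,
    switch_period: int = 20,
    initial_side: str = "left",
    sigma: float = 0.05,
    alpha_W: float = 0.1,
    gamma: float = 0.95,
    eps_a: float = 0.9,
    eps_b: float = 0.8,
    eps_floor: float = 0.1,
    max_steps: int = 500,
    engine: str = "numba",
) -> list[RunResult]:
    """Run every (lambda, alpha_r) configuration ``n_runs`` times.

    Returns ``len(lams) * len(alpha_rs) * n_runs`` RunResults in grid order
    (lambda outermost, run index innermost).  Per-run seeds derive from
    ``(base_seed, lambda, alpha_r, run_id)`` only.
    """
    lams = list(lams)
    alpha_rs = list(alpha_rs)
    if not lams or not alpha_rs:
        raise ValueError("hyperparameter grids must be non-empty")
    if len(set(lams)) != len(lams) or len(set(alpha_rs)) != len(alpha_rs):
        raise ValueError("duplicate values in a hyperparameter grid")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if layout is None:
        layout = build_layout()

    results: list[RunResult] = []
    n_configs = len(lams) * len(alpha_rs)
    config_no = 0
    for lam in lams:
        for alpha_r in alpha_rs:
            config_no += 1
            for run_id in range(n_runs):
                seed = run_seed(base_seed, lam, alpha_r, run_id)
                params = AgentParams(
                    alpha_r=alpha_r,
                    lam=lam,
                    alpha_W=alpha_W,
                    gamma=gamma,
                    sigma=sigma,
                    eps_a=eps_a,
                    eps_b=eps_b,
                    eps_floor=eps_floor,
                    max_steps=max_steps,
                    seed=seed,
                )
                results.append(
                    run_trial(
                        params,
                        layout=layout,
                        n_episodes=n_episodes,
                        switch_period=switch_period,
                        initial_side=initial_side,
                        run_id=run_id,
                        engine=engine,
                    )
                )
            logger.info(
                "config %d/%d done (lam=%.1f, alpha_r=%.1f, %d runs)",
                config_no,
                n_configs,
                lam,
                alpha_r,
                n_runs,
            )
    return results


def episodes_frame(results: Iterable[RunResult]):
    """Long-format per-episode log as a DataFrame (one row per episode)."""
    import pandas as pd

    rows = []
    for run in results:
        for ep in run.episodes:
            rows.append(
                (
                    run.lam,
                    run.alpha_r,
                    run.run_id,
                    run.seed,
                    ep.episode_index,
                    ep.goal_side,
                    ep.steps,
                    ep.reward,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "lam",
            "alpha_r",
            "run_id",
            "seed",
            "episode",
            "goal_side",
            "steps",
            "reward",
        ],
    )
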