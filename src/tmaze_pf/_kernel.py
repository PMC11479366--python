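"""Compiled inner loop for whole-trial simulation.

This replays, step for step and random draw for random draw, exactly the
sequence of operations of the pure-Python reference path in
:mod:`tmaze_pf.experiment` (observation noise, epsilon-greedy draws, TD
updates, blocked-move and terminal conventions), so the two engines produce
bit-identical trajectories from the same seeded generator.  The equivalence
is asserted by the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _fill_observation(o, feat_idx, sigma, rng, d):
    if sigma > 0.0:
        for i in range(d):
            o[i] = sigma * rng.standard_normal()
    else:
        for i in range(d):
            o[i] = 0.0
    o[feat_idx] = o[feat_idx] + 1.0


@njit(cache=True)
def run_trial_kernel(
    W,
    wr,
    succ,
    feat,
    start_state,
    goal_states,
    goal_side_idx,
    eps_by_episode,
    sigma,
    gamma,
    lam,
    alpha_W,
    alpha_r,
    max_steps,
    rng,
):
    """Simulate one full trial (sequence of episodes) in place.

    ``W`` and ``wr`` are updated in place; returns per-episode step counts
    and rewards.  ``succ`` is the (n_states, 4) deterministic successor
    table (self where the move is blocked), ``feat`` maps state index ->
    one-hot coordinate, ``goal_states`` holds the state index of the
    left/right goal, and ``goal_side_idx`` selects the active one per
    episode.  Blocked moves learn as self-transitions but do not consume
    the ``max_steps`` budget; the bootstrap is zeroed on episode-ending
    transitions.
    """
    n_episodes = goal_side_idx.shape[0]
    d = W.shape[0]
    n_actions = succ.shape[1]
    gl = gamma * lam

    e = np.zeros(d)
    o_t = np.empty(d)
    o_t1 = np.empty(d)
    steps_out = np.empty(n_episodes, dtype=np.int64)
    reward_out = np.empty(n_episodes, dtype=np.int64)

    for k in range(n_episodes):
        eps = eps_by_episode[k]
        goal = goal_states[goal_side_idx[k]]
        s = start_state
        for i in range(d):
            e[i] = 0.0
        _fill_observation(o_t, feat[s], sigma, rng, d)
        steps = 0
        done = False
        r = 0.0

        while not done:
            # epsilon-greedy: always two uniform draws per decision
            if rng.random() < eps:
                a = int(rng.random() * n_actions)
            else:
                col_values = np.dot(wr, W)
                q_max = -np.inf
                for j in range(n_actions):
                    q_j = col_values[feat[succ[s, j]]]
                    if q_j > q_max:
                        q_max = q_j
                n_ties = 0
                for j in range(n_actions):
                    if col_values[feat[succ[s, j]]] == q_max:
                        n_ties += 1
                pick = int(rng.random() * n_ties)
                a = 0
                seen = 0
                for j in range(n_actions):
                    if col_values[feat[succ[s, j]]] == q_max:
                        if seen == pick:
                            a = j
                            break
                        seen += 1

            s2 = succ[s, a]
            blocked = s2 == s
            s = s2
            if not blocked:
                steps += 1
                if s == goal:
                    r = 1.0
                    done = True
                elif steps >= max_steps:
                    r = 0.0
                    done = True
                else:
                    r = 0.0
            else:
                r = 0.0

            _fill_observation(o_t1, feat[s], sigma, rng, d)

            # TD(lambda) update, mirroring agent.td_update operation order
            for i in range(d):
                e[i] = e[i] + o_t[i]
            bootstrap = 0.0 if done else gamma
            W_o1 = np.dot(W, o_t1)
            W_o = np.dot(W, o_t)
            delta_r = r - np.dot(o_t1, wr)
            c = alpha_r * delta_r
            for i in range(d):
                dpf_i = o_t[i] + bootstrap * W_o1[i] - W_o[i]
                for j in range(d):
                    W[i, j] = W[i, j] + alpha_W * (dpf_i * e[j])
            for i in range(d):
                wr[i] = wr[i] + c * o_t1[i]
            for i in range(d):
                e[i] = e[i] * gl

            tmp = o_t
            o_t = o_t1
            o_t1 = tmp

        steps_out[k] = steps
        reward_out[k] = 1 if r == 1.0 else 0

    return steps_out, reward_out
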