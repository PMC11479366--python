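"""Tabular successor/predecessor-feature TD(lambda) agent.

The agent factorises the value function through a successor-feature matrix
``W`` and a reward-weight vector ``wr``:

    V(s) = psi(s) . wr,   psi(s) = W phi(s),

where ``phi(s)`` is the (possibly noise-corrupted) one-hot state feature.
``W`` is learned with TD(lambda) via an eligibility trace ``e``; lambda = 0
recovers plain successor features (TD(0)), lambda > 0 gives predecessor
features, whose traces propagate TD errors back to recently visited states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maze import ACTIONS, EnvState, MazeLayout


@dataclass(frozen=True)
class AgentParams:
    """All agent hyperparameters.

    ``alpha_r`` (reward learning rate) and ``lam`` (trace decay) are the two
    swept hyperparameters; the rest are held fixed across the study:
    feature-weight learning rate ``alpha_W`` = 0.1, discount ``gamma`` = 0.95,
    observation noise ``sigma`` = 0.05, and the epsilon-greedy schedule
    eps(k) = eps_a * eps_b**k + eps_floor = 0.9 * 0.8**k + 0.1 over episodes.
    """

    alpha_r: float
    lam: float
    alpha_W: float = 0.1
    gamma: float = 0.95
    sigma: float = 0.05
    eps_a: float = 0.9
    eps_b: float = 0.8
    eps_floor: float = 0.1
    max_steps: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam < 1.0:
            raise ValueError("lam must lie in [0, 1)")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie in (0, 1)")
        if self.alpha_r <= 0 or self.alpha_W <= 0:
            raise ValueError("learning rates must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


@dataclass
class AgentWeights:
    """Learned state: SF/PF matrix W (d x d), reward vector wr, trace e."""

    W: np.ndarray
    wr: np.ndarray
    e: np.ndarray

    @property
    def d(self) -> int:
        return self.wr.shape[0]


@dataclass(frozen=True)
class TDDeltas:
    """TD errors of one update: vector-valued for W, scalar for wr."""

    delta_pf: np.ndarray
    delta_r: float


def init_weights(d: int, rng: np.random.Generator) -> AgentWeights:
    """W entries i.i.d. Uniform[0,1); wr and e start at zero."""
    if d < 1:
        raise ValueError("d must be >= 1")
    return AgentWeights(W=rng.random((d, d)), wr=np.zeros(d), e=np.zeros(d))


def epsilon(episode_index: int, params: AgentParams) -> float:
    """Exploration probability for an episode; geometric decay to the floor.

    Constant within an episode and never reset at goal relocations.
    """
    if episode_index < 0:
        raise ValueError("episode_index must be non-negative")
    return params.eps_a * params.eps_b**episode_index + params.eps_floor


def state_value(weights: AgentWeights, obs: np.ndarray) -> float:
    """V(o) = (W o) . wr."""
    if obs.shape != (weights.d,):
        raise ValueError(f"observation must have length {weights.d}")
    return float(np.dot(np.dot(weights.W, obs), weights.wr))


def td_update(
    weights: AgentWeights,
    o_t: np.ndarray,
    o_t1: np.ndarray,
    r: float,
    params: AgentParams,
    terminal: bool = False,
) -> tuple[AgentWeights, TDDeltas]:
    """One TD(lambda) update on the transition (o_t, o_t1, r); in place.

    Order of operations:

        e      <- e + o_t
        dpf    <- o_t + gamma W o_t1 - W o_t
        dr     <- r - o_t1 . wr
        W      <- W + alpha_W (dpf outer e)
        wr     <- wr + alpha_r dr o_t1
        e      <- gamma lambda e

    ``dpf`` indexes rows of the W update and the trace ``e`` columns, matching
    the ``W o`` convention of :func:`state_value`.  The reward error is
    evaluated at the arrived-at observation ``o_t1``, which also carries the
    reward-weight update.

    On episode-ending transitions (``terminal=True``) the bootstrap term
    ``gamma W o_t1`` is dropped, the usual episodic-TD convention: there is
    no future occupancy beyond an absorbing state, and without the cut the
    successor features of states near the goal inflate without bound.
    """
    d = weights.d
    if o_t.shape != (d,) or o_t1.shape != (d,):
        raise ValueError(f"observations must have length {d}")
    weights.e += o_t
    bootstrap = 0.0 if terminal else params.gamma
    delta_pf = o_t + bootstrap * np.dot(weights.W, o_t1) - np.dot(weights.W, o_t)
    delta_r = float(r - np.dot(o_t1, weights.wr))
    weights.W += params.alpha_W * np.outer(delta_pf, weights.e)
    weights.wr += (params.alpha_r * delta_r) * o_t1
    weights.e *= params.gamma * params.lam
    return weights, TDDeltas(delta_pf=delta_pf, delta_r=delta_r)


def q_values(
    weights: AgentWeights, state: EnvState, layout: MazeLayout
) -> dict[str, float]:
    """Action values by one-step lookahead through the known dynamics.

    Q(a) is the learned value of the deterministic successor cell of action
    ``a`` (the current cell if the move is blocked), evaluated on the clean
    one-hot feature of that cell: observation noise perturbs learning, not
    action evaluation.  With one-hot candidates, W phi(s') is just a column
    of W, so Q(a) = wr . W[:, j(s')] -- computed for all cells at once as
    wr W.
    """
    if state.position not in layout.state_index:
        raise ValueError(f"position {state.position} is not on the corridor")
    col_values = np.dot(weights.wr, weights.W)
    q: dict[str, float] = {}
    for action in ACTIONS:
        succ = layout.successor(state.position, action)
        q[action] = float(col_values[layout.feature_index(succ)])
    return q


def select_action(
    q: dict[str, float], eps: float, rng: np.random.Generator
) -> str:
    """Epsilon-greedy draw: explore uniformly, else argmax with uniform tie-break.

    Always consumes exactly two uniform variates (branch indicator, then the
    action or tie-break draw), so the random stream advances identically on
    both branches -- a requirement for the compiled run loop to replay the
    exact same trajectory.
    """
    if not q:
        raise ValueError("q must be non-empty")
    if not 0.0 <= eps <= 1.0:
        raise ValueError("eps must lie in [0, 1]")
    actions = list(q)
    if rng.random() < eps:
        return actions[int(rng.random() * len(actions))]
    values = list(q.values())
    q_max = max(values)
    ties = [a for a, v in zip(actions, values) if v == q_max]
    return ties[int(rng.random() * len(ties))]
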