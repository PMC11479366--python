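"""Agent primitives: initialisation, schedule, values, TD(lambda) updates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmaze_pf import (
    AgentParams,
    AgentWeights,
    epsilon,
    init_weights,
    q_values,
    reset_env,
    select_action,
    state_value,
    td_update,
)
from .oracles import trace_bruteforce


def make_params(**kwargs):
    defaults = dict(alpha_r=0.5, lam=0.4)
    defaults.update(kwargs)
    return AgentParams(**defaults)


class TestInitWeights:
    def test_seeded_determinism_and_shapes(self):
        w1 = init_weights(17, np.random.default_rng(7))
        w2 = init_weights(17, np.random.default_rng(7))
        np.testing.assert_array_equal(w1.W, w2.W)
        assert w1.W.shape == (17, 17)
        assert np.all((w1.W >= 0) & (w1.W < 1))
        np.testing.assert_array_equal(w1.wr, np.zeros(17))
        np.testing.assert_array_equal(w1.e, np.zeros(17))

    def test_invalid_dimension(self, rng):
        with pytest.raises(ValueError):
            init_weights(0, rng)


class TestEpsilon:
    def test_schedule_values(self):
        params = make_params()
        assert epsilon(0, params) == 1.0
        assert epsilon(1, params) == pytest.approx(0.82)
        assert epsilon(500, params) == pytest.approx(0.1)

    def test_negative_index_rejected(self):
        with pytest.raises(ValueError):
            epsilon(-1, make_params())


class TestStateValue:
    def test_identity_sr_reduces_to_reward(self):
        d = 5
        wr = np.zeros(d)
        wr[3] = 1.0
        w = AgentWeights(W=np.eye(d), wr=wr, e=np.zeros(d))
        goal_obs = np.eye(d)[3]
        other_obs = np.eye(d)[0]
        assert state_value(w, goal_obs) == 1.0
        assert state_value(w, other_obs) == 0.0

    def test_hand_example(self):
        w = AgentWeights(
            W=np.array([[0.1, 0.0], [0.0, 0.0]]),
            wr=np.array([0.0, 0.5]),
            e=np.zeros(2),
        )
        assert state_value(w, np.array([1.0, 0.0])) == 0.0

    def test_dimension_mismatch(self):
        w = AgentWeights(W=np.zeros((3, 3)), wr=np.zeros(3), e=np.zeros(3))
        with pytest.raises(ValueError):
            state_value(w, np.zeros(4))


class TestTDUpdate:
    def test_hand_computed_single_transition(self):
        """Line-by-line arithmetic of one update from zero weights."""
        w = AgentWeights(W=np.zeros((2, 2)), wr=np.zeros(2), e=np.zeros(2))
        params = make_params(alpha_r=0.5, lam=0.5, alpha_W=0.1, gamma=0.95)
        o_t = np.array([1.0, 0.0])
        o_t1 = np.array([0.0, 1.0])
        _, deltas = td_update(w, o_t, o_t1, 1.0, params)
        np.testing.assert_array_equal(deltas.delta_pf, [1.0, 0.0])
        assert deltas.delta_r == 1.0
        np.testing.assert_allclose(w.W, [[0.1, 0.0], [0.0, 0.0]])
        np.testing.assert_allclose(w.wr, [0.0, 0.5])
        np.testing.assert_allclose(w.e, [0.475, 0.0])

    def test_zero_error_is_fixed_point(self):
        d = 3
        # W and wr consistent with a zero-reward self-loop: all zeros
        w = AgentWeights(W=np.zeros((d, d)), wr=np.zeros(d), e=np.zeros(d))
        params = make_params(lam=0.0)
        o = np.zeros(d)
        _, deltas = td_update(w, o, o, 0.0, params)
        np.testing.assert_array_equal(deltas.delta_pf, np.zeros(d))
        assert deltas.delta_r == 0.0
        np.testing.assert_array_equal(w.W, np.zeros((d, d)))
        np.testing.assert_array_equal(w.wr, np.zeros(d))

    def test_lambda_zero_clears_trace(self, rng):
        w = init_weights(4, rng)
        params = make_params(lam=0.0)
        td_update(w, rng.standard_normal(4), rng.standard_normal(4), 0.0, params)
        np.testing.assert_array_equal(w.e, np.zeros(4))

    def test_terminal_drops_bootstrap(self, rng):
        params = make_params()
        o_t, o_t1 = rng.standard_normal(4), rng.standard_normal(4)
        w_term = init_weights(4, np.random.default_rng(3))
        W0 = w_term.W.copy()
        _, deltas = td_update(w_term, o_t, o_t1, 1.0, params, terminal=True)
        np.testing.assert_allclose(deltas.delta_pf, o_t - W0 @ o_t)

    def test_dimension_mismatch(self, rng):
        w = init_weights(4, rng)
        with pytest.raises(ValueError):
            td_update(w, np.zeros(3), np.zeros(4), 0.0, make_params())

    @given(
        lam=st.sampled_from([0.0, 0.2, 0.5, 0.8]),
        n_steps=st.integers(1, 20),
        seed=st.integers(0, 10_000),
    )
    @settings(derandomize=True, max_examples=40)
    def test_trace_equals_decayed_sum(self, lam, n_steps, seed):
        """After t steps, e = sum over i<=t of (gamma*lam)**(t-i) * o_i."""
        rng = np.random.default_rng(seed)
        params = make_params(lam=lam)
        w = init_weights(3, rng)
        observations = [rng.standard_normal(3) for _ in range(n_steps + 1)]
        for o_t, o_t1 in zip(observations, observations[1:]):
            td_update(w, o_t, o_t1, 0.0, params)
        # trace after the final decay: one extra gamma*lam factor
        expected = params.gamma * params.lam * trace_bruteforce(
            observations[:-1], params.gamma, params.lam
        )
        np.testing.assert_allclose(w.e, expected, rtol=1e-12, atol=1e-12)


class TestQValues:
    def test_zero_weights_give_zero_everywhere(self, layout):
        w = AgentWeights(W=np.zeros((17, 17)), wr=np.zeros(17), e=np.zeros(17))
        state = reset_env(layout, 0, "left")
        assert set(q_values(w, state, layout).values()) == {0.0}

    def test_goal_adjacent_prefers_goal_action(self, layout):
        d = layout.d
        wr = np.zeros(d)
        wr[layout.feature_index(layout.goal_left)] = 1.0
        w = AgentWeights(W=np.eye(d), wr=wr, e=np.zeros(d))
        state = reset_env(layout, 0, "left")
        state.position = (0, 1)
        q = q_values(w, state, layout)
        assert max(q, key=q.get) == "left"

    def test_blocked_action_values_current_cell(self, layout, rng):
        w = init_weights(layout.d, rng)
        w.wr[:] = rng.standard_normal(layout.d)
        state = reset_env(layout, 0, "left")  # (8,4): "down" is blocked
        q = q_values(w, state, layout)
        col_values = w.wr @ w.W
        assert q["down"] == col_values[layout.feature_index((8, 4))]


class TestSelectAction:
    def test_pure_exploration_is_uniform(self, rng):
        q = {"up": 5.0, "down": 0.0, "left": 0.0, "right": 0.0}
        picks = [select_action(q, 1.0, rng) for _ in range(10_000)]
        freqs = {a: picks.count(a) / 10_000 for a in q}
        for f in freqs.values():
            assert abs(f - 0.25) < 0.02

    def test_pure_exploitation_unique_max(self, rng):
        q = {"up": 0.0, "down": 2.0, "left": 1.0, "right": -1.0}
        assert all(select_action(q, 0.0, rng) == "down" for _ in range(100))

    def test_ties_break_uniformly(self, rng):
        q = {"up": 1.0, "down": 1.0, "left": 0.0, "right": 0.0}
        picks = [select_action(q, 0.0, rng) for _ in range(10_000)]
        assert abs(picks.count("up") / 10_000 - 0.5) < 0.02
        assert picks.count("left") == 0

    def test_empty_q_rejected(self, rng):
        with pytest.raises(ValueError):
            select_action({}, 0.5, rng)
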