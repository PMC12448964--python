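"""Student model: logistic step success, episode simulation, TD updates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oclshape import (
    StudentParams,
    StudentState,
    bias_from_action_count,
    episode_success_prob,
    logistic_success_prob,
    run_episode,
    run_interaction,
)


class TestLogisticSuccess:
    @pytest.mark.parametrize(
        "q, eps, expected",
        [
            (0.0, 0.0, 0.5),
            (0.0, -1.7, 0.15446527),   # the ~15% naive rate at the failure boundary
            (2.0, -2.0, 0.5),
        ],
    )
    def test_values(self, q, eps, expected):
        assert logistic_success_prob(q, eps) == pytest.approx(expected, abs=1e-7)

    @pytest.mark.parametrize("n_actions", [2, 3, 5, 10])
    def test_uniform_policy_bias_gives_one_over_k(self, n_actions):
        eps = bias_from_action_count(n_actions)
        assert logistic_success_prob(0.0, eps) == pytest.approx(1.0 / n_actions)

    def test_bias_values(self):
        assert bias_from_action_count(2) == 0.0
        assert bias_from_action_count(5) == pytest.approx(-math.log(4))

    def test_bias_rejects_single_action(self):
        with pytest.raises(ValueError):
            bias_from_action_count(1)

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            logistic_success_prob(float("nan"), 0.0)
        with pytest.raises(ValueError):
            logistic_success_prob(0.0, float("inf"))

    @given(
        q=st.floats(-15, 15), eps=st.floats(-15, 15),
        dq=st.floats(0.01, 2), deps=st.floats(0.01, 2),
    )
    @settings(max_examples=50, derandomize=True)
    def test_monotone_and_bounded(self, q, eps, dq, deps):
        p = logistic_success_prob(q, eps)
        assert 0.0 < p < 1.0
        assert logistic_success_prob(q + dq, eps) >= p
        assert logistic_success_prob(q, eps + deps) >= p


class TestEpisodeSuccessProb:
    def test_closed_form_product(self):
        params = StudentParams.constant_bias(6, -1.0, 0.1)
        state = StudentState.naive(6)
        sig = logistic_success_prob(0.0, -1.0)
        for k in range(1, 7):
            assert episode_success_prob(state, params, k) == pytest.approx(sig**k)

    def test_single_unbiased_step_is_half(self):
        params = StudentParams.constant_bias(3, 0.0, 0.1)
        assert episode_success_prob(StudentState.naive(3), params, 1) == 0.5

    def test_limit_high_q(self):
        params = StudentParams.constant_bias(4, -1.0, 0.1)
        state = StudentState(q=np.full(4, 50.0))
        assert episode_success_prob(state, params, 4) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("k", [0, 5])
    def test_level_out_of_range(self, k):
        params = StudentParams.constant_bias(4, 0.0, 0.1)
        with pytest.raises(ValueError):
            episode_success_prob(StudentState.naive(4), params, k)

    @given(k=st.integers(1, 7))
    @settings(max_examples=20, derandomize=True)
    def test_non_increasing_in_level(self, k):
        rng = np.random.default_rng(3)
        params = StudentParams(n_steps=8, eps=rng.normal(-1, 0.5, 8), alpha=0.1)
        state = StudentState(q=rng.normal(0, 1, 8))
        assert (episode_success_prob(state, params, k + 1)
                <= episode_success_prob(state, params, k))


class TestRunEpisode:
    def test_zero_learning_rate_leaves_state_unchanged(self, rng):
        params = StudentParams.constant_bias(5, -0.5, 0.0)
        state = StudentState.naive(5)
        for _ in range(20):
            run_episode(state, params, 4, rng(11))
        assert np.all(state.q == 0.0)

    def test_monte_carlo_matches_analytic_probability(self, rng):
        # alpha=0 student: empirical frequency within 3 binomial SE of product form
        params = StudentParams.constant_bias(4, -0.8, 0.0)
        state = StudentState(q=np.array([0.5, 0.0, 1.0, -0.2]))
        p = episode_success_prob(state, params, 4)
        n = 20000
        g = rng(21)
        wins = sum(run_episode(state, params, 4, g)[0].outcome for _ in range(n))
        se = math.sqrt(p * (1 - p) / n)
        assert abs(wins / n - p) < 3 * se

    def test_unit_reward_success_update(self, scripted_rng):
        # single-step task, forced success, reward magnitude 1: q1 <- alpha
        params = StudentParams.constant_bias(1, 0.0, 0.3, reward=1.0)
        state = StudentState.naive(1)
        res, _ = run_episode(state, params, 1, scripted_rng([0.1]))
        assert res.outcome == 1
        assert state.q[0] == pytest.approx(0.3)

    def test_extinction_after_increment(self, scripted_rng):
        # level just raised k -> k+1: correct through k, fail at k+1 lowers q_k
        params = StudentParams.constant_bias(3, 0.0, 0.1)
        state = StudentState(q=np.array([2.0, 1.5, 0.0]))
        res, _ = run_episode(state, params, 3, scripted_rng([0.0, 0.0, 0.99]))
        assert res.outcome == 0 and res.steps_taken == 3
        assert state.q[1] < 1.5  # pulled toward the untrained q_3 = 0

    def test_outcome_consistency(self, rng):
        params = StudentParams.constant_bias(4, -0.5, 0.2)
        state = StudentState.naive(4)
        g = rng(31)
        for _ in range(200):
            res, _ = run_episode(state, params, 3, g)
            assert res.outcome == int(res.steps_taken == 3 and res.trace[-1])
            assert all(res.trace[:-1])

    def test_values_beyond_level_never_touched(self, rng):
        params = StudentParams.constant_bias(6, -0.5, 0.5)
        state = StudentState.naive(6)
        g = rng(41)
        for _ in range(300):
            run_episode(state, params, 3, g)
        assert np.all(state.q[3:] == 0.0)

    def test_invalid_level_rejected(self, rng):
        params = StudentParams.constant_bias(3, 0.0, 0.1)
        with pytest.raises(ValueError):
            run_episode(StudentState.naive(3), params, 4, rng(1))


class TestRunInteraction:
    def test_deterministic_success_block(self, rng):
        params = StudentParams.constant_bias(2, 30.0, 0.0)
        block, state = run_interaction(StudentState.naive(2), params, 2, 3, rng(5))
        assert block.tolist() == [1, 1, 1]
        assert np.all(state.q == 0.0)

    def test_block_length(self, rng):
        params = StudentParams.constant_bias(2, 0.0, 0.1)
        for n in (1, 7, 25):
            block, _ = run_interaction(StudentState.naive(2), params, 1, n, rng(6, n))
            assert len(block) == n

    def test_naive_rate_at_boundary_bias(self, rng):
        # eps = -1.7, no learning: ~15% success at a single step
        params = StudentParams.constant_bias(1, -1.7, 0.0)
        g = rng(7)
        outcomes = [run_interaction(StudentState.naive(1), params, 1, 10, g)[0].mean()
                    for _ in range(400)]
        p = 0.15446527
        se = math.sqrt(p * (1 - p) / 4000)
        assert abs(np.mean(outcomes) - p) < 3 * se

    def test_reproducible_under_seed(self, rng):
        params = StudentParams.constant_bias(4, -1.0, 0.1)
        b1, s1 = run_interaction(StudentState.naive(4), params, 3, 50, rng(8))
        b2, s2 = run_interaction(StudentState.naive(4), params, 3, 50, rng(8))
        assert np.array_equal(b1, b2) and np.array_equal(s1.q, s2.q)


class TestParamsValidation:
    def test_eps_broadcast_and_roundtrip(self):
        p = StudentParams.constant_bias(4, -1.2, 0.1)
        assert p.eps.shape == (4,)
        q = StudentParams.from_dict(p.to_dict())
        assert np.array_equal(p.eps, q.eps) and q.alpha == p.alpha

    def test_heterogeneous_biases_supported(self):
        p = StudentParams(n_steps=3, eps=[-1.0, -2.0, 0.5], alpha=0.2)
        assert p.eps.tolist() == [-1.0, -2.0, 0.5]
        d = p.to_dict()
        assert d["eps"] == [-1.0, -2.0, 0.5]

    @pytest.mark.parametrize("bad", [{"n_steps": 0, "eps": 0, "alpha": 0.1},
                                     {"n_steps": 2, "eps": 0, "alpha": 1.5}])
    def test_invalid_params(self, bad):
        with pytest.raises(ValueError):
            StudentParams(n_steps=bad["n_steps"], eps=bad["eps"], alpha=bad["alpha"])
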