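"""Q-learning updates, policy extraction, and the value-iteration oracle."""

import numpy as np
import pandas as pd
import pytest

from htndtr import policy_learning as pl
from htndtr.errors import ConfigurationError
from htndtr.reward_model import RewardConfig


def _sample(s, a, r, s2):
    return pl.TransitionSample(s, a, r, s2)


class TestQUpdate:
    def test_printed_overwrite_rule(self):
        # alpha = 1, r = 1, gamma = 0.9, max next Q = 2 -> 2.8
        q = pl.QTable.zeros(4, 3)
        q.values[2] = [0.0, 2.0, 1.0]
        params = pl.LearnParams(gamma=0.9, learning_rate=1.0)
        pl.q_update(q, _sample(0, 1, 1.0, 2), params)
        assert q.values[0, 0] == pytest.approx(2.8)
        assert q.counts[0, 0] == 1

    def test_myopic_limit(self):
        q = pl.QTable.zeros(4, 3)
        q.values[1] = [5.0, 5.0, 5.0]
        params = pl.LearnParams(gamma=0.0, learning_rate=1.0)
        pl.q_update(q, _sample(0, 2, 0.7, 1), params)
        assert q.values[0, 1] == pytest.approx(0.7)

    def test_convex_combination(self):
        q = pl.QTable.zeros(4, 3)
        q.values[0, 0] = 2.0
        q.values[2] = [0.0, 2.0, 0.0]
        params = pl.LearnParams(gamma=0.9, learning_rate=0.5)
        pl.q_update(q, _sample(0, 1, 1.0, 2), params)
        assert q.values[0, 0] == pytest.approx(0.5 * 2.0 + 0.5 * 2.8)

    def test_out_of_range_sample(self):
        q = pl.QTable.zeros(4, 3)
        with pytest.raises(ConfigurationError):
            pl.q_update(q, _sample(0, 4, 1.0, 0), pl.LearnParams())


class TestEpsilonGreedy:
    def test_near_zero_epsilon_is_greedy(self):
        q = pl.QTable.zeros(2, 14)
        q.values[0] = np.arange(14)
        params = pl.LearnParams(epsilon=1e-12)
        rng = np.random.default_rng(0)
        assert all(
            pl.epsilon_greedy(q, 0, params, rng) == 14 for _ in range(50)
        )

    def test_tie_breaks_to_lowest_action(self):
        q = pl.QTable.zeros(2, 14)
        params = pl.LearnParams(epsilon=1e-12)
        rng = np.random.default_rng(0)
        assert pl.epsilon_greedy(q, 0, params, rng) == 1

    def test_epsilon_one_is_uniform(self):
        q = pl.QTable.zeros(1, 14)
        q.values[0, 3] = 100.0  # greedy branch never taken
        params = pl.LearnParams(epsilon=1.0)
        rng = np.random.default_rng(123)
        draws = np.array(
            [pl.epsilon_greedy(q, 0, params, rng) for _ in range(10_000)]
        )
        freq = np.bincount(draws, minlength=15)[1:] / 10_000
        p = 1 / 14
        se = np.sqrt(p * (1 - p) / 10_000)
        assert np.all(np.abs(freq - p) < 3 * se)


class TestFitQLearning:
    def test_single_sample_myopic_converges_in_one_sweep(self):
        samples = [_sample(0, 1, 0.6, 1)]
        params = pl.LearnParams(
            gamma=0.0, learning_rate=1.0, polyak_tail=0.0, max_sweeps=10,
            tolerance=1e-9,
        )
        q = pl.fit_q_learning(samples, params, n_states=2, n_actions=1)
        assert q.values[0, 0] == pytest.approx(0.6)
        assert q.converged and q.n_sweeps == 2  # second sweep sees no change

    def test_empty_sample_set_rejected(self):
        with pytest.raises(ConfigurationError):
            pl.fit_q_learning([], pl.LearnParams())

    def test_small_mdp_matches_value_iteration(self):
        rng = np.random.default_rng(42)
        P, R = pl.random_mdp(4, 3, rng)
        samples = pl.exhaustive_samples(P, R, denominator=20, repeats=3)
        vi = pl.value_iteration(P, R, gamma=0.9)
        params = pl.LearnParams(
            gamma=0.9, learning_rate=None, polyak_tail=0.5, max_sweeps=1500,
            seed=1,
        )
        q = pl.fit_q_learning(samples, params)
        policy = pl.greedy_policy(q, restrict_to_observed=False)
        assert np.array_equal(
            policy.action_by_state, vi.policy.action_by_state
        )
        assert np.abs(q.values - vi.q_values).max() < 0.01

    def test_reward_linearity_alpha_one(self):
        """Doubling all rewards doubles the fitted table exactly on the
        overwrite (alpha = 1) path with identical sweep order."""
        rng = np.random.default_rng(3)
        P, R = pl.random_mdp(5, 3, rng)
        samples = pl.exhaustive_samples(P, R, denominator=20)
        doubled = samples.assign(reward_value=2 * samples["reward_value"])
        params = pl.LearnParams(
            gamma=0.9, learning_rate=1.0, polyak_tail=0.0, max_sweeps=80,
            seed=9,
        )
        q1 = pl.fit_q_learning(samples, params)
        q2 = pl.fit_q_learning(doubled, params)
        assert np.allclose(q2.values, 2 * q1.values)

    def test_reward_scale_invariance_of_policy(self):
        rng = np.random.default_rng(8)
        P, R = pl.random_mdp(6, 4, rng)
        samples = pl.exhaustive_samples(P, R, denominator=20, repeats=2)
        scaled = samples.assign(reward_value=7.0 * samples["reward_value"])
        params = pl.LearnParams(
            gamma=0.9, learning_rate=None, polyak_tail=0.5, max_sweeps=600,
            seed=4,
        )
        p1 = pl.greedy_policy(
            pl.fit_q_learning(samples, params), restrict_to_observed=False
        )
        p2 = pl.greedy_policy(
            pl.fit_q_learning(scaled, params), restrict_to_observed=False
        )
        assert np.array_equal(p1.action_by_state, p2.action_by_state)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(12)
        P, R = pl.random_mdp(4, 2, rng)
        samples = pl.exhaustive_samples(P, R, denominator=20)
        params = pl.LearnParams(max_sweeps=40, seed=5)
        q1 = pl.fit_q_learning(samples, params)
        q2 = pl.fit_q_learning(samples, params)
        assert np.array_equal(q1.values, q2.values)


class TestGreedyPolicy:
    def test_argmax_with_tie_break(self):
        q = pl.QTable.zeros(2, 3)
        q.values[0] = [3.0, 5.0, 1.0]
        q.counts[:] = 1
        policy = pl.greedy_policy(q, restrict_to_observed=False)
        assert policy[0] == 2
        assert policy[1] == 1  # all-zero row ties to lowest id

    def test_restricted_mode_uses_only_observed_actions(self):
        q = pl.QTable.zeros(1, 14)
        q.values[0] = np.linspace(1, 14, 14)
        q.counts[0, 6] = 1  # only action 7 observed
        policy = pl.greedy_policy(q, restrict_to_observed=True)
        assert policy[0] == 7

    def test_unobserved_state_left_undefined(self):
        q = pl.QTable.zeros(2, 3)
        q.counts[0, 0] = 2
        policy = pl.greedy_policy(q, restrict_to_observed=True)
        assert policy[1] is None and not policy.defined[1]

    def test_restricted_differs_only_on_unvisited_pairs(self):
        rng = np.random.default_rng(31)
        q = pl.QTable.zeros(20, 5)
        q.values[:] = rng.normal(size=(20, 5))
        q.counts[:] = (rng.random((20, 5)) < 0.6).astype(int)
        free = pl.greedy_policy(q, restrict_to_observed=False)
        restricted = pl.greedy_policy(q, restrict_to_observed=True)
        differ = np.nonzero(
            free.action_by_state != restricted.action_by_state
        )[0]
        for s in differ:
            assert q.counts[s, free.action_by_state[s] - 1] == 0

    def test_min_support_excludes_thin_actions(self):
        q = pl.QTable.zeros(1, 3)
        q.values[0] = [1.0, 50.0, 2.0]
        q.counts[0] = [40, 1, 30]  # action 2: single lucky sample
        assert pl.greedy_policy(q, True, min_support=5)[0] == 3
        assert pl.greedy_policy(q, True, min_support=1)[0] == 2


class TestTransitionModel:
    def test_degenerate_mle(self):
        samples = [_sample(0, 1, 1.0, 3)] * 10
        P, R, counts = pl.estimate_transition_model(
            samples, n_states=108, n_actions=14, smoothing=0.0
        )
        assert P[0, 0, 3] == 1.0
        assert R[0, 0] == 1.0
        assert counts[0, 0] == 10

    def test_add_k_smoothing_arithmetic(self):
        samples = [_sample(0, 1, 1.0, 3)] * 10
        P, _, _ = pl.estimate_transition_model(
            samples, n_states=108, n_actions=14, smoothing=0.5
        )
        assert P[0, 0, 3] == pytest.approx(10.5 / (10 + 0.5 * 108))
        assert P[0, 0, 5] == pytest.approx(0.5 / (10 + 0.5 * 108))

    def test_rows_normalized(self):
        rng = np.random.default_rng(77)
        df = pd.DataFrame(
            {
                "state_index": rng.integers(0, 6, 500),
                "action_id": rng.integers(1, 4, 500),
                "reward_value": rng.normal(size=500),
                "next_state_index": rng.integers(0, 6, 500),
            }
        )
        P, _, _ = pl.estimate_transition_model(df, n_states=6, n_actions=3)
        assert np.allclose(P.sum(axis=2), 1.0)


class TestValueIteration:
    def test_myopic_closed_form(self):
        rng = np.random.default_rng(1)
        P, R = pl.random_mdp(5, 3, rng)
        vi = pl.value_iteration(P, R, gamma=0.0)
        assert np.allclose(vi.q_values, R)

    def test_geometric_series_chain(self):
        # 2 states, 1 action, reward 1 everywhere: V = 1 / (1 - 0.9) = 10
        P = np.zeros((2, 1, 2))
        P[0, 0, 1] = 1.0
        P[1, 0, 0] = 1.0
        R = np.ones((2, 1))
        vi = pl.value_iteration(P, R, gamma=0.9, tolerance=1e-12)
        assert np.allclose(vi.q_values, 10.0, atol=1e-9)

    def test_residuals_contract_at_gamma(self):
        rng = np.random.default_rng(10)
        P, R = pl.random_mdp(8, 3, rng)
        vi = pl.value_iteration(P, R, gamma=0.9)
        resid = np.array(vi.residuals)
        nonzero = resid[:-1] > 1e-8
        ratios = resid[1:][nonzero] / resid[:-1][nonzero]
        assert np.all(ratios <= 0.9 * (1 + 1e-5))

    def test_gamma_one_rejected(self):
        P = np.ones((1, 1, 1))
        with pytest.raises(ConfigurationError):
            pl.value_iteration(P, np.ones((1, 1)), gamma=1.0)


class TestExtractTransitions:
    def test_consecutive_pairs_and_rewards(self, small_dataset, small_visits):
        samples = pl.extract_transitions(small_visits, RewardConfig())
        n, h = (
            small_dataset.trajectories.n_patients,
            small_dataset.trajectories.horizon,
        )
        assert len(samples) == n * (h - 1)
        states = small_dataset.trajectories.states
        actions = small_dataset.trajectories.actions
        grouped = samples.groupby("patient_id")
        first = samples.iloc[0]
        assert first["state_index"] == states[0, 0]
        assert first["action_id"] == actions[0, 0]
        assert first["next_state_index"] == states[0, 1]
        assert (grouped.size() == h - 1).all()

    def test_single_visit_patients_contribute_nothing(self):
        visits = pd.DataFrame(
            {
                "patient_id": [1, 2, 2],
                "date": pd.to_datetime(
                    ["2004-01-01", "2004-01-01", "2004-05-01"]
                ),
                "state_index": [0, 1, 2],
                "action_id": pd.array([1, 2, 3], dtype="Int64"),
            }
        )
        samples = pl.extract_transitions(visits, RewardConfig())
        assert list(samples["patient_id"]) == [2]
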