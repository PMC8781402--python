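"""Value iteration as baseline and as oracle for the Q-learning fit.

First solves a small random MDP exactly and shows the sweep-based
learner reaching the same greedy policy; then fits the empirical-model
baseline (maximum-likelihood transitions + value iteration) that the
recommender is compared against.
"""

import numpy as np

from htndtr import policy_learning as pl

rng = np.random.default_rng(0)
P, R = pl.random_mdp(n_states=6, n_actions=3, rng=rng)
vi = pl.value_iteration(P, R, gamma=0.9)
print(f"value iteration: {len(vi.residuals)} backups, "
      f"final residual {vi.residuals[-1]:.2e}")

samples = pl.exhaustive_samples(P, R, denominator=20, repeats=3)
params = pl.LearnParams(
    gamma=0.9, learning_rate=None, polyak_tail=0.5, max_sweeps=1500, seed=1
)
q = pl.fit_q_learning(samples, params)
policy = pl.greedy_policy(q, restrict_to_observed=False)
same = np.array_equal(policy.action_by_state, vi.policy.action_by_state)
print(f"Q-learning on {len(samples)} replicated samples reaches the "
      f"value-iteration policy: {same}")
print(f"max |Q - Q*| = {np.abs(q.values - vi.q_values).max():.2e}")

# The same machinery doubles as the empirical-MDP baseline: estimate the
# model from data with add-k smoothing, then solve it.
P_hat, R_hat, counts = pl.estimate_transition_model(
    samples, n_states=6, n_actions=3
)
baseline = pl.value_iteration(P_hat, R_hat, gamma=0.9)
agree = np.mean(
    baseline.policy.action_by_state == vi.policy.action_by_state
)
print(f"baseline (smoothed empirical model) agrees with the exact policy "
      f"on {100 * agree:.0f}% of states")
print("Interpretation: with exhaustive data both routes coincide; on"
      " sparse clinical records the smoothed baseline degrades faster"
      " than the sweep-based learner, which is why the two are compared.")
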