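"""Offline tabular Q-learning and the empirical-MDP baseline.

The learner consumes (state, action, reward, next-state) experience tuples
extracted from consecutive patient visits and repeatedly sweeps them in a
seeded shuffled order, applying the stochastic-approximation form of the
Q-value backup

    Q(s, a) <- (1 - alpha) Q(s, a) + alpha [ r + gamma max_a' Q(s', a') ]

With ``alpha = 1`` this is the plain overwrite backup; a fractional or
decaying step size is required for convergence on stochastic offline data.
The greedy policy of the converged table is the treatment recommendation.

The baseline fits a maximum-likelihood transition/reward model from the
same samples and solves it by value iteration; ``value_iteration`` doubles
as the exact oracle against which the sweep-based learner is tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import numba
import numpy as np
import pandas as pd

from .cohort_builder import N_ACTIONS, N_STATES
from .errors import ConfigurationError
from .reward_model import RewardConfig, reward_matrix

logger = logging.getLogger(__name__)


class TransitionSample(NamedTuple):
    """One (s, a, r, s') experience from a pair of consecutive visits."""

    state_index: int
    action_id: int
    reward_value: float
    next_state_index: int
    patient_id: object = None
    epoch_index: int = 0


@dataclass
class LearnParams:
    """Hyper-parameters of the offline Q-learning fit.

    ``learning_rate`` is the constant step size alpha; set it to ``None``
    to decay per state–action visit count as ``N(s,a) ** -lr_exponent``.
    ``polyak_tail`` > 0 averages the Q iterate over the trailing fraction
    of sweeps (Polyak–Ruppert), which removes the residual oscillation of
    a non-vanishing step size; early stopping is disabled in that mode.
    ``epsilon`` only matters for interactive action selection
    (:func:`epsilon_greedy`); the offline fit sweeps recorded samples.
    ``restrict_to_observed``/``min_support`` govern policy extraction:
    recommendations are limited to actions with data support in the
    state (see :func:`greedy_policy`).
    """

    gamma: float = 0.9
    epsilon: float = 0.1
    learning_rate: float | None = None
    lr_exponent: float = 0.6
    polyak_tail: float = 0.5
    max_sweeps: int = 60
    tolerance: float = 1e-4
    seed: int = 0
    restrict_to_observed: bool = True
    min_support: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ConfigurationError("gamma must be in [0, 1]")
        if not 0.0 < self.epsilon <= 1.0:
            raise ConfigurationError("epsilon must be in (0, 1]")
        if self.learning_rate is not None and not (
            0.0 < self.learning_rate <= 1.0
        ):
            raise ConfigurationError("learning_rate must be in (0, 1]")
        if not 0.0 <= self.polyak_tail <= 1.0:
            raise ConfigurationError("polyak_tail must be in [0, 1]")
        if self.max_sweeps < 1:
            raise ConfigurationError("max_sweeps must be >= 1")


@dataclass
class QTable:
    """State x action value table with per-pair visit counts."""

    values: np.ndarray
    counts: np.ndarray
    converged: bool = False
    n_sweeps: int = 0

    @classmethod
    def zeros(cls, n_states: int = N_STATES, n_actions: int = N_ACTIONS):
        return cls(
            values=np.zeros((n_states, n_actions)),
            counts=np.zeros((n_states, n_actions), dtype=np.int64),
        )

    @property
    def n_states(self) -> int:
        return self.values.shape[0]

    @property
    def n_actions(self) -> int:
        return self.values.shape[1]


@dataclass
class Policy:
    """Greedy state -> action map; 0 marks states with no recommendation."""

    action_by_state: np.ndarray

    def __getitem__(self, state_index: int) -> int | None:
        a = int(self.action_by_state[state_index])
        return a if a > 0 else None

    @property
    def defined(self) -> np.ndarray:
        return self.action_by_state > 0

    @property
    def n_states(self) -> int:
        return self.action_by_state.shape[0]


# ---------------------------------------------------------------------------
# Sample handling


def extract_transitions(
    visits: pd.DataFrame, reward_config: RewardConfig = RewardConfig()
) -> pd.DataFrame:
    """Turn consecutive visit pairs into (s, a, r, s') samples.

    A pair contributes iff the earlier visit has a prescribed action; the
    reward is computed from the action and the *resulting* state.  Patients
    with fewer than two visits contribute nothing.
    """
    v = visits.sort_values(["patient_id", "date"], kind="mergesort")
    grp = v.groupby("patient_id")
    nxt_state = grp["state_index"].shift(-1)
    keep = nxt_state.notna() & v["action_id"].notna()
    if not keep.any():
        raise ConfigurationError("no usable transitions in visit table")

    s = v.loc[keep, "state_index"].to_numpy(dtype=np.int64)
    a = v.loc[keep, "action_id"].to_numpy(dtype=np.int64)
    s2 = nxt_state[keep].to_numpy(dtype=np.int64)
    rmat = reward_matrix(reward_config)
    out = pd.DataFrame(
        {
            "patient_id": v.loc[keep, "patient_id"].to_numpy(),
            "epoch_index": grp.cumcount()[keep].to_numpy(),
            "state_index": s,
            "action_id": a,
            "reward_value": rmat[s2, a - 1],
            "next_state_index": s2,
        }
    )
    return out.reset_index(drop=True)


def _as_arrays(samples) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(samples, pd.DataFrame):
        if len(samples) == 0:
            raise ConfigurationError("empty sample set")
        return (
            samples["state_index"].to_numpy(dtype=np.int64),
            samples["action_id"].to_numpy(dtype=np.int64),
            samples["reward_value"].to_numpy(dtype=np.float64),
            samples["next_state_index"].to_numpy(dtype=np.int64),
        )
    samples = list(samples)
    if not samples:
        raise ConfigurationError("empty sample set")
    arr = np.array(
        [
            (t.state_index, t.action_id, t.reward_value, t.next_state_index)
            for t in samples
        ],
        dtype=np.float64,
    )
    return (
        arr[:, 0].astype(np.int64),
        arr[:, 1].astype(np.int64),
        arr[:, 2],
        arr[:, 3].astype(np.int64),
    )


# ---------------------------------------------------------------------------
# Q-learning


def q_update(
    q: QTable, sample: TransitionSample, params: LearnParams
) -> QTable:
    """Apply one backup in place and return the table.

    With ``learning_rate=1`` this is exactly the overwrite backup
    ``Q(s,a) <- r + gamma max_a' Q(s',a')``.
    """
    s, a = int(sample.state_index), int(sample.action_id)
    if not 0 <= s < q.n_states or not 1 <= a <= q.n_actions:
        raise ConfigurationError(f"sample indices out of range: {sample}")
    n = q.counts[s, a - 1] + 1
    alpha = (
        float(n) ** -params.lr_exponent
        if params.learning_rate is None
        else params.learning_rate
    )
    target = sample.reward_value + params.gamma * q.values[
        int(sample.next_state_index)
    ].max()
    q.values[s, a - 1] += alpha * (target - q.values[s, a - 1])
    q.counts[s, a - 1] = n
    return q


@numba.njit(cache=False)
def _sweep(
    values, counts, s, a, r, s2, order, gamma, alpha_const, lr_exponent
):  # pragma: no cover - exercised through fit_q_learning
    max_delta = 0.0
    n_actions = values.shape[1]
    for k in range(order.shape[0]):
        i = order[k]
        si = s[i]
        ai = a[i] - 1
        qnext = values[s2[i], 0]
        for j in range(1, n_actions):
            if values[s2[i], j] > qnext:
                qnext = values[s2[i], j]
        n = counts[si, ai] + 1
        if alpha_const > 0.0:
            alpha = alpha_const
        else:
            alpha = float(n) ** (-lr_exponent)
        old = values[si, ai]
        new = old + alpha * (r[i] + gamma * qnext - old)
        values[si, ai] = new
        counts[si, ai] = n
        delta = new - old
        if delta < 0.0:
            delta = -delta
        if delta > max_delta:
            max_delta = delta
    return max_delta


def fit_q_learning(
    samples,
    params: LearnParams = LearnParams(),
    n_states: int | None = None,
    n_actions: int | None = None,
) -> QTable:
    """Fit the Q-table by seeded shuffled sweeps over the sample set.

    Sweeping stops when the largest absolute Q change over a full sweep
    drops below ``params.tolerance`` or after ``params.max_sweeps`` sweeps
    (with ``polyak_tail > 0`` all sweeps are run and the returned values
    are the average of the trailing-fraction iterates).  Deterministic
    given ``params.seed``.
    """
    s, a, r, s2 = _as_arrays(samples)
    if n_states is None:
        n_states = int(max(s.max(), s2.max())) + 1
    if n_states <= max(s.max(), s2.max()):
        raise ConfigurationError("state index outside declared state space")
    if n_actions is None:
        n_actions = int(a.max())
    if a.min() < 1 or a.max() > n_actions:
        raise ConfigurationError("action id outside declared action space")

    q = QTable.zeros(n_states, n_actions)
    # q.counts reports data support (visits per pair); the step-size decay
    # runs on cumulative update counts across sweeps.
    np.add.at(q.counts, (s, a - 1), 1)
    update_counts = np.zeros_like(q.counts)
    rng = np.random.default_rng(params.seed)
    alpha_const = params.learning_rate if params.learning_rate else -1.0

    tail_start = (
        int(np.ceil((1.0 - params.polyak_tail) * params.max_sweeps))
        if params.polyak_tail > 0
        else params.max_sweeps
    )
    avg = np.zeros_like(q.values)
    n_avg = 0

    delta = np.inf
    sweep = 0
    for sweep in range(1, params.max_sweeps + 1):
        order = rng.permutation(len(s))
        delta = _sweep(
            q.values,
            update_counts,
            s,
            a,
            r,
            s2,
            order,
            params.gamma,
            float(alpha_const),
            params.lr_exponent,
        )
        if sweep > tail_start:
            if n_avg:
                prev = avg / n_avg
                delta = float(
                    np.abs((avg + q.values) / (n_avg + 1) - prev).max()
                )
            avg += q.values
            n_avg += 1
        if params.polyak_tail == 0 and delta < params.tolerance:
            break

    if n_avg:
        q.values = avg / n_avg
    # with tail averaging, convergence is judged on the averaged iterate
    q.converged = bool(delta < params.tolerance)
    q.n_sweeps = sweep
    if not q.converged and params.polyak_tail == 0:
        logger.warning(
            "Q-learning stopped after %d sweeps with max |dQ| = %.3g "
            "(tolerance %.3g)", sweep, delta, params.tolerance,
        )
    return q


def epsilon_greedy(
    q: QTable,
    state_index: int,
    params: LearnParams,
    rng: np.random.Generator,
) -> int:
    """Greedy action with probability 1 - epsilon, else uniform over all.

    Greedy ties break toward the lowest action id.  Returns an action id.
    """
    if rng.random() < 1.0 - params.epsilon:
        return int(np.argmax(q.values[state_index])) + 1
    return int(rng.integers(q.n_actions)) + 1


def greedy_policy(
    q: QTable, restrict_to_observed: bool = True, min_support: int = 1
) -> Policy:
    """Per-state argmax of the Q-table (ties -> lowest action id).

    With ``restrict_to_observed`` the argmax runs over actions observed
    in that state; states with no observed action are left without a
    recommendation.  ``min_support`` strengthens the restriction: an
    action needs at least that many recorded visits to be recommendable
    (capped at the state's best-supported action count, so a state whose
    only action was seen once still gets that action).  A Q estimate
    backed by one or two transitions is a single noisy draw, and letting
    it win the argmax is how offline learners latch onto flukes.
    """
    values = q.values
    if restrict_to_observed:
        support = np.minimum(min_support, q.counts.max(axis=1))[:, None]
        values = np.where(q.counts >= np.maximum(support, 1), q.values, -np.inf)
    actions = np.argmax(values, axis=1).astype(np.int64) + 1
    if restrict_to_observed:
        actions[~(q.counts > 0).any(axis=1)] = 0
    return Policy(actions)


# ---------------------------------------------------------------------------
# Empirical MDP baseline


def estimate_transition_model(
    samples,
    n_states: int = N_STATES,
    n_actions: int = N_ACTIONS,
    smoothing: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximum-likelihood transition tensor and mean-reward table.

    Transition rows get add-k smoothing over next states:
    ``P(s'|s,a) = (n(s,a,s') + k) / (n(s,a) + k * S)``.  State–action
    pairs never observed get a uniform row and zero reward.  Returns
    ``(P, R, counts)`` with shapes (S, A, S), (S, A), (S, A).
    """
    s, a, r, s2 = _as_arrays(samples)
    counts3 = np.zeros((n_states, n_actions, n_states))
    np.add.at(counts3, (s, a - 1, s2), 1.0)
    counts = counts3.sum(axis=2)

    rsum = np.zeros((n_states, n_actions))
    np.add.at(rsum, (s, a - 1), r)

    observed = counts > 0
    P = np.full((n_states, n_actions, n_states), 1.0 / n_states)
    numer = counts3 + smoothing
    denom = counts + smoothing * n_states
    P[observed] = numer[observed] / denom[observed, None]

    R = np.zeros((n_states, n_actions))
    R[observed] = rsum[observed] / counts[observed]
    return P, R, counts.astype(np.int64)


class VIResult(NamedTuple):
    q_values: np.ndarray
    policy: Policy
    residuals: list[float]


def value_iteration(
    transition_tensor: np.ndarray,
    reward_table: np.ndarray,
    gamma: float = 0.9,
    tolerance: float = 1e-9,
    max_iter: int = 100_000,
) -> VIResult:
    """Solve the MDP by Bellman-optimality backups.

    Iterates ``Q <- R + gamma * P max_a Q`` until the sup-norm change is
    below ``tolerance``; the residual trajectory is returned so the
    gamma-contraction of the backup can be inspected.
    """
    if gamma >= 1.0:
        raise ConfigurationError(
            "value iteration requires gamma < 1 for non-episodic dynamics"
        )
    P = np.asarray(transition_tensor, dtype=float)
    R = np.asarray(reward_table, dtype=float)
    if not np.allclose(P.sum(axis=2), 1.0, atol=1e-6):
        raise ConfigurationError("transition tensor rows must sum to 1")

    Q = np.zeros_like(R)
    residuals: list[float] = []
    for _ in range(max_iter):
        V = Q.max(axis=1)
        Q_new = R + gamma * P @ V
        resid = float(np.abs(Q_new - Q).max())
        residuals.append(resid)
        Q = Q_new
        if resid < tolerance:
            break
    policy = Policy(np.argmax(Q, axis=1).astype(np.int64) + 1)
    return VIResult(Q, policy, residuals)


# ---------------------------------------------------------------------------
# Small random MDPs (oracle-equivalence checks)


def random_mdp(
    n_states: int,
    n_actions: int,
    rng: np.random.Generator,
    transition_denominator: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """A random finite MDP with rational transition probabilities.

    Each transition row is ``multinomial(d, Dirichlet(1)) / d`` so that a
    sample set can replicate it exactly; rewards are deterministic per
    (s, a), uniform on [0, 1].
    """
    d = transition_denominator
    P = np.zeros((n_states, n_actions, n_states))
    for s in range(n_states):
        for a in range(n_actions):
            w = rng.dirichlet(np.ones(n_states))
            P[s, a] = rng.multinomial(d, w) / d
    R = rng.uniform(size=(n_states, n_actions))
    return P, R


def exhaustive_samples(
    P: np.ndarray, R: np.ndarray, denominator: int = 20, repeats: int = 1
) -> pd.DataFrame:
    """A sample set whose empirical frequencies equal ``P`` exactly.

    ``P`` must have entries that are multiples of ``1/denominator`` (as
    from :func:`random_mdp`); each (s, a, s') appears with multiplicity
    proportional to its probability, ``repeats`` times.
    """
    n_states, n_actions, _ = P.shape
    denom = denominator
    rows = []
    for s in range(n_states):
        for a in range(n_actions):
            counts = P[s, a] * denom
            if not np.allclose(counts, np.round(counts), atol=1e-6):
                raise ConfigurationError(
                    "transition probabilities are not multiples of a "
                    "common denominator"
                )
            for s2, c in enumerate(np.round(counts).astype(int)):
                for _ in range(c * repeats):
                    rows.append((s, a + 1, R[s, a], s2))
    return pd.DataFrame(
        rows,
        columns=["state_index", "action_id", "reward_value",
                 "next_state_index"],
    )
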