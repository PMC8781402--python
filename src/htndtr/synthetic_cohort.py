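"""Synthetic claims-style cohort generator with a planted treatment response.

Real claims data behind this kind of study cannot be redistributed, so the
package ships a generative stand-in: a ground-truth Markov decision process
over the 108 discrete patient states whose planted structure mirrors the
clinical escalation logic — the therapy tier (mono/dual/triple) appropriate
for a state is determined by a severity score, and prescribing the
appropriate regimen maximises the probability that the patient's state
improves.  A noisy "doctor" behaviour policy generates visit trajectories,
which are then rendered into the three raw record tables (check-ups,
diagnosis claims, prescriptions) that the cohort builder consumes.

Planted structure
-----------------
* severity = 3 * complications + bp_level + 1{bmi_level == 2}; the
  appropriate tier is mono (severity <= 1), dual (2–3) or triple (>= 4),
  and the canonical regimen is the lowest action id of that tier.
* Action quality q(s, a) is 1 for the canonical regimen, lower for other
  regimens of the right tier, and much lower for the wrong tier; the
  probabilities of BP/BMI improvement rise with q, the probabilities of
  worsening and of complication onset fall with q.  All action dependence
  is scaled by ``appropriateness_strength`` (0 = actions have no effect).
* Complications are absorbing; age flag and diabetes-duration level are
  static over a follow-up window (the window is short enough that neither
  crosses a category boundary, enforced by config validation).
* Doctors prescribe the canonical regimen, deviating uniformly over all
  14 regimens with a probability that scales ``doctor_noise`` by the
  patient's diabetes-duration level (0.5x short, 1.0x medium, 2.5x long):
  prescribing variability is higher for long-standing, complex disease
  histories.  Duration is static within a follow-up window and has no
  effect on the treatment-response dynamics, so deviation is exogenous
  to the health trajectory — the planted dose-response between policy
  concordance and outcomes is causal, not confounded.

Continuous measurements are emitted inside the numeric range of each
visit's discretized component so that re-discretization by the cohort
builder recovers the simulated state index exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .cohort_builder import (
    ACTION_BY_ID,
    N_ACTIONS,
    N_STATES,
    StateVector,
    decode_state,
    encode_state,
)
from .errors import ConfigurationError
from .reward_model import DEFAULT_DECREMENTS, multiplier_vector

#: Longest follow-up window (days) for which the diabetes-duration band is
#: guaranteed constant; 4-year bands minus sampling margins.
_MAX_WINDOW_DAYS = int(3.6 * 365.25)

_CANONICAL_BY_TIER = {1: 1, 2: 5, 3: 11}
_NOISE_WEIGHT_BY_PERIOD = {0: 0.5, 1: 1.0, 2: 2.5}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs of the synthetic cohort."""

    n_patients: int = 2000
    horizon: int = 8
    appropriateness_strength: float = 0.8
    doctor_noise: float = 0.2
    visit_interval_days: int = 120
    adherence_range: tuple[float, float] = (0.25, 0.9)
    entry_start: str = "2003-01-01"
    entry_end: str = "2008-12-31"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.horizon < 2:
            raise ConfigurationError("horizon must be >= 2")
        for name in ("appropriateness_strength", "doctor_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        lo, hi = self.adherence_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ConfigurationError("adherence_range must be in (0, 1]")
        if self.visit_interval_days < 1:
            raise ConfigurationError("visit_interval_days must be >= 1")
        window = (self.horizon - 1) * self.visit_interval_days
        if window > _MAX_WINDOW_DAYS:
            raise ConfigurationError(
                f"follow-up window of {window} days exceeds "
                f"{_MAX_WINDOW_DAYS} days; the diabetes-duration category "
                "would cross a 4-year band within one window"
            )

    @property
    def window_years(self) -> float:
        return (self.horizon - 1) * self.visit_interval_days / 365.25


@dataclass
class GroundTruthMDP:
    """The simulator's full specification of the environment."""

    transition_tensor: np.ndarray  # (108, 14, 108)
    behavior_policy: np.ndarray  # (108, 14)
    initial_distribution: np.ndarray  # (108,)
    seed: int = 0

    def __post_init__(self) -> None:
        P, B, mu = (
            self.transition_tensor,
            self.behavior_policy,
            self.initial_distribution,
        )
        if P.shape != (N_STATES, N_ACTIONS, N_STATES):
            raise ConfigurationError("transition tensor has wrong shape")
        if np.any(P < 0) or np.any(B < 0) or np.any(mu < 0):
            raise ConfigurationError("probabilities must be non-negative")
        if not np.allclose(P.sum(axis=2), 1.0, atol=1e-9):
            raise ConfigurationError("transition rows must sum to 1")
        if not np.allclose(B.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("behaviour-policy rows must sum to 1")
        if not np.isclose(mu.sum(), 1.0, atol=1e-9):
            raise ConfigurationError("initial distribution must sum to 1")

    def tensor_hash(self) -> str:
        h = hashlib.sha256()
        for arr in (
            self.transition_tensor,
            self.behavior_policy,
            self.initial_distribution,
        ):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()


class Trajectories(NamedTuple):
    """Simulated visit sequences: (n_patients, horizon) index arrays."""

    states: np.ndarray
    actions: np.ndarray
    entry_dates: np.ndarray  # datetime64[D], per patient
    visit_interval_days: int

    @property
    def n_patients(self) -> int:
        return self.states.shape[0]

    @property
    def horizon(self) -> int:
        return self.states.shape[1]

    def visit_dates(self) -> np.ndarray:
        """(n_patients, horizon) matrix of visit dates."""
        offsets = np.arange(self.horizon) * self.visit_interval_days
        return self.entry_dates[:, None] + offsets[None, :].astype(
            "timedelta64[D]"
        )


# ---------------------------------------------------------------------------
# Planted policy


def severity_score(state: StateVector) -> int:
    """Severity 0–6 driving the appropriate therapy tier."""
    return 3 * state.complications + state.bp_level + (
        1 if state.bmi_level == 2 else 0
    )


def appropriate_tier(state: StateVector) -> int:
    sev = severity_score(state)
    if sev <= 1:
        return 1
    if sev <= 3:
        return 2
    return 3


def tier_appropriate_policy():
    """The planted optimal policy: canonical regimen of the state's tier."""
    from .policy_learning import Policy

    actions = np.array(
        [
            _CANONICAL_BY_TIER[appropriate_tier(decode_state(i))]
            for i in range(N_STATES)
        ],
        dtype=np.int64,
    )
    return Policy(actions)


def action_quality(state: StateVector, action_id: int) -> float:
    """Match quality q(s, a) in [0, 1]; strictly maximal at the canonical
    regimen of the state's appropriate tier."""
    tier_star = appropriate_tier(state)
    tier = ACTION_BY_ID[action_id].tier
    gap = abs(tier - tier_star)
    if gap == 0:
        return 1.0 if action_id == _CANONICAL_BY_TIER[tier_star] else 0.35
    if gap == 1:
        return 0.2
    return 0.0


# ---------------------------------------------------------------------------
# Ground-truth construction

# Baseline and action-driven transition rates.  All action dependence is
# proportional to appropriateness_strength so that strength 0 removes any
# effect of the action on the next state.
_BP_DOWN = (0.10, 0.55)  # (base, strength*q gain)
_BP_UP = (0.04, 0.38)  # (base, strength*(1-q) gain)
_BMI_DOWN = (0.03, 0.10)
_BMI_UP = (0.03, 0.08)
_COMP_HAZARD = (0.005, 0.075)  # scaled by (1 + bp_level)

#: Initial state distribution: product over independent components
#: (complications, age flag, duration level, BP level, BMI level).
_INIT_COMP = (0.85, 0.15)
_INIT_AGE = (0.65, 0.35)  # P(flag=0), P(flag=1): an older cohort
_INIT_PERIOD = (0.40, 0.35, 0.25)
_INIT_BP = (0.35, 0.40, 0.25)
_INIT_BMI = (0.10, 0.45, 0.45)


def _step_distribution(level: int, p_down: float, p_up: float, n: int = 3):
    """Birth–death step on {0..n-1}: down/up with the given probabilities,
    excess mass stays."""
    dist = np.zeros(n)
    dist[level] = 1.0
    if level > 0:
        dist[level] -= p_down
        dist[level - 1] += p_down
    if level < n - 1:
        dist[level] -= p_up
        dist[level + 1] += p_up
    return dist


def build_ground_truth_mdp(config: SimulationConfig) -> GroundTruthMDP:
    """Construct the planted treatment-response MDP for ``config``.

    Deterministic given the config (the tensor is parametric; the seed is
    carried along for the downstream sampling stages).
    """
    strength = config.appropriateness_strength
    P = np.zeros((N_STATES, N_ACTIONS, N_STATES))
    B = np.zeros((N_STATES, N_ACTIONS))

    for s_idx in range(N_STATES):
        state = decode_state(s_idx)
        tier_star = appropriate_tier(state)
        for action_id in range(1, N_ACTIONS + 1):
            q = action_quality(state, action_id)
            p_bp_dn = _BP_DOWN[0] + _BP_DOWN[1] * strength * q
            p_bp_up = _BP_UP[0] + _BP_UP[1] * strength * (1.0 - q)
            p_bmi_dn = _BMI_DOWN[0] + _BMI_DOWN[1] * strength * q
            p_bmi_up = _BMI_UP[0] + _BMI_UP[1] * strength * (1.0 - q)
            hazard = (
                _COMP_HAZARD[0] + _COMP_HAZARD[1] * strength * (1.0 - q)
            ) * (1 + state.bp_level)

            bp_dist = _step_distribution(state.bp_level, p_bp_dn, p_bp_up)
            bmi_dist = _step_distribution(state.bmi_level, p_bmi_dn, p_bmi_up)
            if state.complications == 1:  # absorbing
                comp_dist = np.array([0.0, 1.0])
            else:
                comp_dist = np.array([1.0 - hazard, hazard])

            for c2 in range(2):
                for b2 in range(3):
                    for m2 in range(3):
                        nxt = encode_state(
                            StateVector(
                                c2,
                                state.age_flag,
                                state.period_level,
                                b2,
                                m2,
                            )
                        )
                        P[s_idx, action_id - 1, nxt] = (
                            comp_dist[c2] * bp_dist[b2] * bmi_dist[m2]
                        )

        deviation = min(
            1.0,
            config.doctor_noise * _NOISE_WEIGHT_BY_PERIOD[state.period_level],
        )
        B[s_idx, :] = deviation / N_ACTIONS
        B[s_idx, _CANONICAL_BY_TIER[tier_star] - 1] += 1.0 - deviation

    mu = np.einsum(
        "c,g,p,b,m->cgpbm",
        np.array(_INIT_COMP),
        np.array(_INIT_AGE),
        np.array(_INIT_PERIOD),
        np.array(_INIT_BP),
        np.array(_INIT_BMI),
    ).reshape(-1)
    # index order (c, g, p, b, m) matches the mixed-radix state encoding
    return GroundTruthMDP(P, B, mu, seed=config.seed)


def expected_next_multiplier(mdp: GroundTruthMDP) -> np.ndarray:
    """E[QALY multiplier of next state | s, a], shape (108, 14)."""
    mult = multiplier_vector(DEFAULT_DECREMENTS)
    return mdp.transition_tensor @ mult


# ---------------------------------------------------------------------------
# Trajectory simulation


def _sample_rows(prob_rows: np.ndarray, rng: np.random.Generator):
    """Draw one category per row of a (n, k) probability matrix."""
    cum = np.cumsum(prob_rows, axis=1)
    u = rng.random(prob_rows.shape[0])
    return (u[:, None] > cum).sum(axis=1)


def simulate_trajectories(
    mdp: GroundTruthMDP, config: SimulationConfig
) -> Trajectories:
    """Roll out ``n_patients`` visit sequences under the behaviour policy."""
    rng = np.random.default_rng([config.seed, 0])
    n, h = config.n_patients, config.horizon

    states = np.zeros((n, h), dtype=np.int64)
    actions = np.zeros((n, h), dtype=np.int64)
    states[:, 0] = _sample_rows(
        np.broadcast_to(mdp.initial_distribution, (n, N_STATES)), rng
    )
    for t in range(h):
        actions[:, t] = (
            _sample_rows(mdp.behavior_policy[states[:, t]], rng) + 1
        )
        if t + 1 < h:
            states[:, t + 1] = _sample_rows(
                mdp.transition_tensor[states[:, t], actions[:, t] - 1], rng
            )

    start = np.datetime64(config.entry_start, "D")
    end = np.datetime64(config.entry_end, "D")
    span = int((end - start) / np.timedelta64(1, "D")) + 1
    entry = start + rng.integers(0, span, size=n).astype("timedelta64[D]")
    return Trajectories(states, actions, entry, config.visit_interval_days)


# ---------------------------------------------------------------------------
# Raw-table emission

# Numeric sampling bands per discretized level, with margins so rounding
# never crosses a category boundary.
_SBP_BAND = {0: (115, 139), 1: (140, 159), 2: (160, 195)}
_DBP_BAND = {0: (72, 88), 1: (82, 98), 2: (88, 115)}
_BMI_BAND = {0: (16.0, 18.4), 1: (18.6, 24.9), 2: (25.1, 38.0)}
_ENTRY_AGE_BAND = {1: (35.0, 50.5), 0: (55.3, 78.0)}
_DIABETES_CODES = ("E10", "E11", "E12", "E13", "E14")
_DIABETES_WEIGHTS = (0.08, 0.72, 0.02, 0.03, 0.15)
_COMPLICATION_EMIT_CODES = ("I11", "I12", "I13")


def _onset_band(period_level: int, window_years: float) -> tuple[float, float]:
    """Feasible years-before-entry of diabetes onset for a duration level."""
    margin = 0.2
    if period_level == 0:
        return margin, 4.0 - window_years - margin
    if period_level == 1:
        return 4.0 + margin, 8.0 - window_years - margin
    return 8.0 + margin, 12.0


def emit_raw_tables(
    trajectories: Trajectories,
    mdp: GroundTruthMDP,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Render trajectories into check-up, claim and prescription tables.

    Continuous measurements are drawn inside the band of each visit's
    discretized component, every patient gets an entry I10 claim and a
    pre-entry diabetes claim at the planted onset date, complication
    states emit an I11/I12/I13 claim at onset of the complication, and
    prescriptions carry the drug classes of the simulated action with
    ``days_supply = visit_interval_days x adherence``.
    """
    rng = np.random.default_rng([config.seed, 1])
    n, h = trajectories.n_patients, trajectories.horizon
    states = trajectories.states
    dates = trajectories.visit_dates()
    pids = np.arange(1, n + 1)

    comp = states // 54
    age_flag = (states % 54) // 27
    period = (states % 27) // 9
    bp = (states % 9) // 3
    bmi = states % 3

    # --- per-patient static draws
    entry_age = np.empty(n)
    for flag, (lo, hi) in _ENTRY_AGE_BAND.items():
        mask = age_flag[:, 0] == flag
        entry_age[mask] = rng.uniform(lo, hi, mask.sum())

    onset_years = np.empty(n)
    for level in range(3):
        lo, hi = _onset_band(level, config.window_years)
        mask = period[:, 0] == level
        onset_years[mask] = rng.uniform(lo, hi, mask.sum())
    onset_dates = trajectories.entry_dates - np.round(
        onset_years * 365.25
    ).astype("timedelta64[D]")

    adherence = rng.uniform(*config.adherence_range, size=n)
    smoke = rng.binomial(1, 0.5, size=n)
    famhx = rng.binomial(1, 0.35, size=n)
    dm_code = rng.choice(_DIABETES_CODES, size=n, p=_DIABETES_WEIGHTS)

    # --- check-ups (one row per visit)
    elapsed_years = (
        np.arange(h) * config.visit_interval_days / 365.25
    )[None, :]
    sbp = np.empty((n, h))
    dbp = np.empty((n, h))
    bmi_val = np.empty((n, h))
    for level in range(3):
        mask = bp == level
        lo, hi = _SBP_BAND[level]
        sbp[mask] = rng.integers(lo, hi + 1, mask.sum())
        lo, hi = _DBP_BAND[level]
        dbp[mask] = rng.integers(lo, hi + 1, mask.sum())
        mask = bmi == level
        lo, hi = _BMI_BAND[level]
        bmi_val[mask] = np.round(rng.uniform(lo, hi, mask.sum()), 1)

    checkups = pd.DataFrame(
        {
            "patient_id": np.repeat(pids, h),
            "date": dates.reshape(-1),
            "systolic_bp": sbp.reshape(-1).astype(np.int64),
            "diastolic_bp": dbp.reshape(-1).astype(np.int64),
            "bmi": bmi_val.reshape(-1),
            "fpg": np.round(
                np.clip(rng.normal(145, 30, n * h), 60, 350), 1
            ),
            "tc": np.round(
                np.clip(rng.normal(188, 40, n * h), 80, 400), 1
            ),
            "smoke": np.repeat(smoke, h),
            "family_history": np.repeat(famhx, h),
            "age_years": np.round(
                (entry_age[:, None] + elapsed_years).reshape(-1), 1
            ),
        }
    )

    # --- claims: diabetes at onset, hypertension at entry, complication at
    # the first visit in a complication state
    claim_frames = [
        pd.DataFrame(
            {
                "patient_id": pids,
                "date": onset_dates,
                "icd10_code": dm_code,
            }
        ),
        pd.DataFrame(
            {
                "patient_id": pids,
                "date": trajectories.entry_dates,
                "icd10_code": "I10",
            }
        ),
    ]
    has_comp = comp.any(axis=1)
    if has_comp.any():
        first_comp_visit = comp[has_comp].argmax(axis=1)
        claim_frames.append(
            pd.DataFrame(
                {
                    "patient_id": pids[has_comp],
                    "date": dates[has_comp, first_comp_visit],
                    "icd10_code": rng.choice(
                        _COMPLICATION_EMIT_CODES, size=int(has_comp.sum())
                    ),
                }
            )
        )
    claims = (
        pd.concat(claim_frames, ignore_index=True)
        .sort_values(["patient_id", "date"], kind="mergesort")
        .reset_index(drop=True)
    )
    claims["date"] = pd.to_datetime(claims["date"])

    # --- prescriptions (one per visit, covering the interval to the next)
    supply = np.maximum(
        1, np.round(config.visit_interval_days * adherence)
    ).astype(np.int64)
    labels = np.array(
        ["+".join(c.value for c in sorted(
            ACTION_BY_ID[aid].drug_classes, key=lambda c: c.value
        )) for aid in range(1, N_ACTIONS + 1)]
    )
    prescriptions = pd.DataFrame(
        {
            "patient_id": np.repeat(pids, h),
            "start_date": dates.reshape(-1),
            "days_supply": np.repeat(supply, h),
            "drug_classes": labels[trajectories.actions.reshape(-1) - 1],
        }
    )
    checkups["date"] = pd.to_datetime(checkups["date"])
    prescriptions["start_date"] = pd.to_datetime(prescriptions["start_date"])
    return checkups, claims, prescriptions


@dataclass
class SimulatedDataset:
    """Convenience bundle: ground truth, trajectories and raw tables."""

    config: SimulationConfig
    mdp: GroundTruthMDP
    trajectories: Trajectories
    checkups: pd.DataFrame
    claims: pd.DataFrame
    prescriptions: pd.DataFrame


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Build the MDP, roll out trajectories and emit the raw tables."""
    mdp = build_ground_truth_mdp(config)
    traj = simulate_trajectories(mdp, config)
    checkups, claims, prescriptions = emit_raw_tables(traj, mdp, config)
    return SimulatedDataset(config, mdp, traj, checkups, claims, prescriptions)
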