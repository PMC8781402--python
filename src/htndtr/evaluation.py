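"""Validation statistics for a fitted recommendation policy.

Four families of checks, mirroring how such a recommender is validated
against observed prescribing:

* state-wise concordance between the model's recommendation and the
  doctors' modal prescription per state;
* medication possession ratio (MPR) of the prescriptions that agree with
  the model, summarised per therapy tier;
* outcome curves over 20%-wide buckets of per-patient concordance with
  the model (complication occurrence, final blood-pressure level);
* the distribution of recommended regimens and the mono/dual/triple mix
  within each level of every state component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_builder import (
    COMPLICATION_CODES,
    N_ACTIONS,
    N_STATES,
    TIER_BY_ACTION_ID,
)
from .errors import ConfigurationError
from .policy_learning import Policy

logger = logging.getLogger(__name__)

TIER_NAMES = {1: "mono", 2: "dual", 3: "triple"}

_STATE_COMPONENTS = (
    "complications",
    "age_flag",
    "period_level",
    "bp_level",
    "bmi_level",
)


@dataclass
class DoctorPolicy:
    """Most frequent prescribed action per state, with support counts."""

    modal_action_by_state: np.ndarray  # 0 where never visited
    support_count_by_state: np.ndarray

    @property
    def as_policy(self) -> Policy:
        return Policy(self.modal_action_by_state)


def doctor_policy(visits: pd.DataFrame, n_states: int = N_STATES) -> DoctorPolicy:
    """Modal prescribed action per state (ties -> lowest action id)."""
    with_action = visits.dropna(subset=["action_id"])
    counts = np.zeros((n_states, N_ACTIONS), dtype=np.int64)
    np.add.at(
        counts,
        (
            with_action["state_index"].to_numpy(dtype=np.int64),
            with_action["action_id"].to_numpy(dtype=np.int64) - 1,
        ),
        1,
    )
    support = counts.sum(axis=1)
    modal = np.argmax(counts, axis=1).astype(np.int64) + 1
    modal[support == 0] = 0
    return DoctorPolicy(modal, support)


def concordance_rate(
    model_policy: Policy,
    doctor: DoctorPolicy | Policy,
    denominator_mode: str = "paper",
) -> tuple[int, float]:
    """Count states where model and doctors pick the same action.

    ``paper`` mode divides by the full 108-state space (states where
    either side is undefined count as unmatched); ``supported`` mode
    divides by the number of states where both are defined.  The percent
    is reported to 2 decimals, truncating the third (92/108 prints as
    85.18, not 85.19).
    """
    other = doctor.as_policy if isinstance(doctor, DoctorPolicy) else doctor
    both = model_policy.defined & other.defined
    matched = int(
        (both & (model_policy.action_by_state == other.action_by_state)).sum()
    )
    if denominator_mode == "paper":
        denominator = model_policy.n_states
    elif denominator_mode == "supported":
        denominator = int(both.sum())
    else:
        raise ConfigurationError(
            f"unknown denominator mode: {denominator_mode!r}"
        )
    if denominator == 0:
        return 0, 0.0
    percent = np.floor(10000.0 * matched / denominator) / 100.0
    return matched, float(percent)


# ---------------------------------------------------------------------------
# Medication possession ratio


def mpr(total_days_supply: float, period_days: float) -> float:
    """100 x supply / period, capped at 100%."""
    if period_days <= 0:
        raise ConfigurationError("period_days must be positive")
    if total_days_supply < 0:
        raise ConfigurationError("days supply must be non-negative")
    return min(100.0, 100.0 * total_days_supply / period_days)


def model_adherence_records(
    visits: pd.DataFrame,
    policy: Policy,
    episode_days: float | None = None,
) -> pd.DataFrame:
    """Per patient-and-tier adherence to model-concordant prescriptions.

    A visit contributes iff its prescribed regimen equals the model's
    recommendation for the visit's state; supply days accumulate over
    those episodes and the covered period is ``episode_days`` per episode
    (inferred as the patient's median visit gap when not given).
    Returns columns ``patient_id, tier, total_days_supply, period_days``.
    """
    v = visits.dropna(subset=["action_id", "days_supply"]).copy()
    rec = policy.action_by_state[v["state_index"].to_numpy(dtype=np.int64)]
    v = v[(rec > 0) & (v["action_id"].to_numpy(dtype=np.int64) == rec)]
    if len(v) == 0:
        return pd.DataFrame(
            columns=["patient_id", "tier", "total_days_supply", "period_days"]
        )

    if episode_days is None:
        gaps = (
            visits.sort_values(["patient_id", "date"], kind="mergesort")
            .groupby("patient_id")["date"]
            .diff()
            .dt.days
        )
        per_patient = gaps.groupby(visits["patient_id"]).median()
        v["_episode_days"] = (
            v["patient_id"].map(per_patient).fillna(gaps.median())
        )
    else:
        v["_episode_days"] = float(episode_days)

    v["tier"] = TIER_BY_ACTION_ID[v["action_id"].to_numpy(dtype=np.int64)]
    out = (
        v.groupby(["patient_id", "tier"])
        .agg(
            total_days_supply=("days_supply", "sum"),
            period_days=("_episode_days", "sum"),
        )
        .reset_index()
    )
    return out


def mpr_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Min/max/mean patient-level MPR per therapy tier (percent).

    Tiers without records are simply absent from the result.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=["min", "max", "mean"])
    r = records.copy()
    r["mpr"] = [
        mpr(s, p) for s, p in zip(r["total_days_supply"], r["period_days"])
    ]
    out = (
        r.groupby("tier")["mpr"]
        .agg(["min", "max", "mean"])
        .rename(index=TIER_NAMES)
    )
    out.index.name = "tier"
    return out


# ---------------------------------------------------------------------------
# Concordance-bucket outcome curves

BUCKET_EDGES = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)
_BUCKET_LABELS = ("[0,20)", "[20,40)", "[40,60)", "[60,80)", "[80,100]")


@dataclass
class ConcordanceBucketCurve:
    """Mean outcome per 20%-wide concordance bucket."""

    bucket_edges: tuple = BUCKET_EDGES
    mean_outcome_per_bucket: np.ndarray = None  # NaN where bucket empty
    n_patients_per_bucket: np.ndarray = None

    @property
    def labels(self) -> tuple:
        return _BUCKET_LABELS

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bucket": self.labels,
                "mean_outcome": self.mean_outcome_per_bucket,
                "n_patients": self.n_patients_per_bucket,
            }
        )


def patient_concordance(visits: pd.DataFrame, policy: Policy) -> pd.Series:
    """Percent of each patient's prescribed visits that match the model.

    Visits where the policy has no recommendation for the state are
    excluded from numerator and denominator; patients with no eligible
    visit are dropped (logged).
    """
    v = visits.dropna(subset=["action_id"])
    rec = policy.action_by_state[v["state_index"].to_numpy(dtype=np.int64)]
    eligible = rec > 0
    v = v[eligible]
    match = v["action_id"].to_numpy(dtype=np.int64) == rec[eligible]
    out = (
        pd.Series(match, index=v["patient_id"].to_numpy())
        .groupby(level=0)
        .mean()
        * 100.0
    )
    n_dropped = visits["patient_id"].nunique() - out.index.nunique()
    if n_dropped:
        logger.info(
            "%d patient(s) had no visit with both a prescription and a "
            "model recommendation; excluded from concordance curves",
            n_dropped,
        )
    out.index.name = "patient_id"
    return out.rename("concordance")


def complication_occurrence(
    claims: pd.DataFrame, visits: pd.DataFrame
) -> pd.Series:
    """1 iff a complication claim occurs strictly after the first visit.

    Baseline complications (claims on or before the first visit) do not
    count as occurrences.
    """
    first_visit = visits.groupby("patient_id")["date"].min()
    codes = claims["icd10_code"].astype(str).str.upper()
    comp_claims = claims[codes.str.startswith(COMPLICATION_CODES)]
    occurred = (
        comp_claims.merge(
            first_visit.rename("first_visit"), on="patient_id", how="inner"
        )
        .assign(_after=lambda d: d["date"] > d["first_visit"])
        .groupby("patient_id")["_after"]
        .any()
    )
    out = pd.Series(0, index=first_visit.index, dtype=np.int64)
    out.loc[occurred.index[occurred]] = 1
    out.index.name = "patient_id"
    return out.rename("complication_occurrence")


def baseline_complication_free(visits: pd.DataFrame) -> pd.Index:
    """Patients with no complication at their first visit.

    Incident-complication analyses are run on this at-risk population:
    a patient who already carries the complication cannot have an
    occurrence, so including them would dilute the curves.
    """
    first = (
        visits.sort_values(["patient_id", "date"], kind="mergesort")
        .groupby("patient_id")["complications"]
        .first()
    )
    return first.index[first == 0]


def final_bp_level(visits: pd.DataFrame) -> pd.Series:
    """Discretized blood-pressure level at each patient's last visit."""
    v = visits.sort_values(["patient_id", "date"], kind="mergesort")
    out = v.groupby("patient_id")["bp_level"].last()
    return out.rename("bp_level")


def mean_bp_level(visits: pd.DataFrame) -> pd.Series:
    """Mean discretized blood-pressure level over all of a patient's visits."""
    return visits.groupby("patient_id")["bp_level"].mean().rename("bp_level")


def bucket_outcomes(
    concordance: pd.Series, outcome: pd.Series
) -> ConcordanceBucketCurve:
    """Average an outcome within 20%-wide concordance buckets.

    Patients present in both series are used; empty buckets get NaN mean
    and zero count.
    """
    joined = pd.concat(
        [concordance.rename("c"), outcome.rename("y")], axis=1, join="inner"
    )
    idx = np.minimum((joined["c"].to_numpy() // 20).astype(int), 4)
    means = np.full(5, np.nan)
    counts = np.zeros(5, dtype=np.int64)
    for b in range(5):
        mask = idx == b
        counts[b] = int(mask.sum())
        if counts[b]:
            means[b] = float(joined["y"].to_numpy()[mask].mean())
    return ConcordanceBucketCurve(BUCKET_EDGES, means, counts)


# ---------------------------------------------------------------------------
# Recommendation distributions


@dataclass
class RecommendationMix:
    """Action frequencies and tier mix of per-visit recommendations."""

    action_share: pd.Series  # % of visits per action id
    tier_share_by_component: pd.DataFrame  # (component, level) x tier %


def recommendation_distributions(
    policy: Policy, visits: pd.DataFrame
) -> RecommendationMix:
    """Distribution of model recommendations over the visit stream.

    ``action_share`` is the percentage of visits on which each of the 14
    regimens is recommended; ``tier_share_by_component`` gives, within
    each level of each state component, the mono/dual/triple percentage
    split of recommendations (rows sum to 100).
    """
    rec = policy.action_by_state[
        visits["state_index"].to_numpy(dtype=np.int64)
    ]
    covered = rec > 0
    v = visits[covered].copy()
    v["_rec"] = rec[covered]
    v["_tier"] = TIER_BY_ACTION_ID[rec[covered]]

    action_share = (
        v["_rec"].value_counts(normalize=True).sort_index() * 100.0
    ).reindex(range(1, N_ACTIONS + 1), fill_value=0.0)
    action_share.index.name = "action_id"

    frames = []
    for comp in _STATE_COMPONENTS:
        share = (
            v.groupby(comp)["_tier"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
            .reindex(columns=[1, 2, 3], fill_value=0.0)
            * 100.0
        )
        share.index = pd.MultiIndex.from_product(
            [[comp], share.index], names=["component", "level"]
        )
        frames.append(share)
    tier_share = pd.concat(frames).rename(columns=TIER_NAMES)
    return RecommendationMix(action_share.rename("percent"), tier_share)
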