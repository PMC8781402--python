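"""Cohort selection and discrete state/action encoding of patient visits.

The decision model lives on a finite grid of patient states.  Each visit is
summarised by five discrete components:

* ``complications`` — 0/1, any hypertensive heart and/or chronic kidney
  disease claim (ICD-10 I11, I12, I13) on or before the visit date;
* ``age_flag`` — 1 if the patient is younger than 55 years at the visit,
  0 otherwise (younger patients carry the lower-risk flag value 1);
* ``period_level`` — 0/1/2, years elapsed since diabetes onset
  (<=4, 4–8, >8);
* ``bp_level`` — 0/1/2, blood-pressure stage (prehypertension, stage 1,
  stage 2), taking the worse of the systolic and diastolic categories;
* ``bmi_level`` — 0/1/2, BMI category (underweight, normal, overweight).

This yields 2 x 2 x 3 x 3 x 3 = 108 states, mixed-radix encoded into an
index in [0, 107].  Treatment actions are the 14 antihypertensive regimens
formed from the four drug classes D, ACEi, ARB and CCB: four monotherapies,
all six pairs and all four triples.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

N_STATES = 108
N_ACTIONS = 14

#: Radix (number of levels) of each state component, most-significant first.
_COMPONENT_LEVELS = (2, 2, 3, 3, 3)

#: ICD-10 codes counted as hypertension-related complications.
COMPLICATION_CODES = ("I11", "I12", "I13")

_ICD10_RE = re.compile(r"^[A-Z]\d{2}")


class StateVector(NamedTuple):
    """Discretized five-component patient state."""

    complications: int
    age_flag: int
    period_level: int
    bp_level: int
    bmi_level: int


class DrugClass(str, Enum):
    """The four antihypertensive drug classes."""

    D = "D"
    ACEI = "ACEi"
    ARB = "ARB"
    CCB = "CCB"


@dataclass(frozen=True)
class Action:
    """One of the 14 prescribable regimens.

    ``tier`` is the number of drug classes combined (1 = monotherapy,
    2 = dual therapy, 3 = triple therapy).
    """

    action_id: int
    drug_classes: frozenset[DrugClass]

    @property
    def tier(self) -> int:
        return len(self.drug_classes)

    @property
    def label(self) -> str:
        order = [DrugClass.ARB, DrugClass.CCB, DrugClass.ACEI, DrugClass.D]
        return " + ".join(c.value for c in order if c in self.drug_classes)


def _mk(action_id: int, *classes: DrugClass) -> Action:
    return Action(action_id, frozenset(classes))


#: The full action space, ordered by id: 1–4 mono, 5–10 dual, 11–14 triple.
ACTIONS: tuple[Action, ...] = (
    _mk(1, DrugClass.ARB),
    _mk(2, DrugClass.CCB),
    _mk(3, DrugClass.ACEI),
    _mk(4, DrugClass.D),
    _mk(5, DrugClass.ARB, DrugClass.CCB),
    _mk(6, DrugClass.CCB, DrugClass.D),
    _mk(7, DrugClass.ACEI, DrugClass.CCB),
    _mk(8, DrugClass.ARB, DrugClass.D),
    _mk(9, DrugClass.ACEI, DrugClass.D),
    _mk(10, DrugClass.ACEI, DrugClass.ARB),
    _mk(11, DrugClass.ARB, DrugClass.CCB, DrugClass.D),
    _mk(12, DrugClass.ACEI, DrugClass.CCB, DrugClass.D),
    _mk(13, DrugClass.ACEI, DrugClass.ARB, DrugClass.CCB),
    _mk(14, DrugClass.ACEI, DrugClass.ARB, DrugClass.D),
)

ACTION_BY_ID: dict[int, Action] = {a.action_id: a for a in ACTIONS}
_ACTION_BY_CLASSES: dict[frozenset[DrugClass], Action] = {
    a.drug_classes: a for a in ACTIONS
}

#: Therapy tier (1/2/3) of every action id, index 0 unused.
TIER_BY_ACTION_ID = np.array([0] + [a.tier for a in ACTIONS], dtype=np.int64)


# ---------------------------------------------------------------------------
# State encoding


def encode_state(state: StateVector) -> int:
    """Mixed-radix index of a state vector, in [0, 107]."""
    c, g, p, b, m = state
    for value, levels in zip(state, _COMPONENT_LEVELS):
        if not 0 <= int(value) < levels:
            raise ConfigurationError(
                f"state component out of range: {state!r}"
            )
    return ((int(c) * 2 + int(g)) * 3 + int(p)) * 9 + int(b) * 3 + int(m)


def decode_state(index: int) -> StateVector:
    """Inverse of :func:`encode_state`."""
    if not 0 <= int(index) < N_STATES:
        raise ConfigurationError(f"state index out of range: {index}")
    index = int(index)
    m = index % 3
    b = (index // 3) % 3
    p = (index // 9) % 3
    g = (index // 27) % 2
    c = index // 54
    return StateVector(c, g, p, b, m)


def all_states() -> list[StateVector]:
    """All 108 state vectors in index order."""
    return [decode_state(i) for i in range(N_STATES)]


def encode_action(drug_classes: Iterable[DrugClass | str]) -> Action:
    """Look up the regimen with exactly this set of drug classes.

    Order is irrelevant; sets of size 0 or 4, or unknown class names,
    raise :class:`ConfigurationError`.
    """
    try:
        classes = frozenset(DrugClass(c) for c in drug_classes)
    except ValueError as exc:
        raise ConfigurationError(f"unknown drug class: {exc}") from exc
    action = _ACTION_BY_CLASSES.get(classes)
    if action is None:
        raise ConfigurationError(
            f"no regimen with class set {sorted(c.value for c in classes)}"
        )
    return action


def parse_drug_classes(label: str) -> frozenset[DrugClass]:
    """Parse a 'ARB+CCB'-style label into a drug-class set."""
    parts = [p.strip() for p in str(label).split("+") if p.strip()]
    if not parts:
        raise ConfigurationError(f"empty drug-class label: {label!r}")
    return frozenset(DrugClass(p) for p in parts)


# ---------------------------------------------------------------------------
# Discretizers.  Each accepts scalars or numpy arrays and is piecewise
# constant and monotone on its valid domain.


def discretize_bp(systolic, diastolic):
    """Blood-pressure level 0/1/2 from a systolic/diastolic reading (mmHg).

    Categories: systolic <140 / 140–159 / >=160 and diastolic <90 /
    90–99 / >=100; the visit level is the worse of the two.  Readings
    below the prehypertensive range map to level 0.
    """
    systolic = np.asarray(systolic, dtype=float)
    diastolic = np.asarray(diastolic, dtype=float)
    if np.any(systolic <= 0) or np.any(diastolic <= 0):
        raise ConfigurationError("blood-pressure readings must be positive")
    sys_cat = np.digitize(systolic, [140.0, 160.0])
    dia_cat = np.digitize(diastolic, [90.0, 100.0])
    level = np.maximum(sys_cat, dia_cat)
    return level if level.ndim else int(level)


def discretize_bmi(bmi):
    """BMI level: [0, 18.5) -> 0, [18.5, 25) -> 1, [25, inf) -> 2."""
    bmi = np.asarray(bmi, dtype=float)
    if np.any(bmi <= 0):
        raise ConfigurationError("BMI must be positive")
    level = np.digitize(bmi, [18.5, 25.0])
    return level if level.ndim else int(level)


def discretize_age(age_years):
    """Age flag: 1 if younger than 55 years, 0 otherwise."""
    age_years = np.asarray(age_years, dtype=float)
    flag = (age_years < 55.0).astype(np.int64)
    return flag if flag.ndim else int(flag)


def discretize_period(years_since_onset):
    """Diabetes-duration level: <=4 y -> 0, (4, 8] y -> 1, >8 y -> 2."""
    years = np.asarray(years_since_onset, dtype=float)
    if np.any(years < 0):
        raise ConfigurationError("diabetes duration must be non-negative")
    level = np.digitize(years, [4.0, 8.0], right=True)
    return level if level.ndim else int(level)


def detect_complication(claims: pd.DataFrame, as_of_date) -> int:
    """1 iff any I11/I12/I13 claim exists on or before ``as_of_date``.

    ``claims`` needs columns ``icd10_code`` and ``date``.
    """
    if len(claims) == 0:
        return 0
    codes = claims["icd10_code"].astype(str).str.upper()
    mask = codes.str.startswith(COMPLICATION_CODES)
    if not mask.any():
        return 0
    dates = pd.to_datetime(claims.loc[mask, "date"])
    return int((dates <= pd.Timestamp(as_of_date)).any())


# ---------------------------------------------------------------------------
# Cohort selection

_CHECKUP_REQUIRED = [
    "systolic_bp",
    "diastolic_bp",
    "bmi",
    "fpg",
    "tc",
    "smoke",
    "family_history",
]


def _valid_claims(claims: pd.DataFrame) -> pd.DataFrame:
    codes = claims["icd10_code"].astype(str).str.strip().str.upper()
    ok = codes.str.match(_ICD10_RE)
    n_bad = int((~ok).sum())
    if n_bad:
        bad = claims.loc[~ok, "icd10_code"].unique()[:5]
        logger.warning(
            "dropping %d claim record(s) with malformed ICD-10 codes "
            "(e.g. %s)", n_bad, list(bad),
        )
    out = claims.loc[ok].copy()
    out["icd10_code"] = codes[ok]
    return out


def select_cohort(
    claims: pd.DataFrame,
    prescriptions: pd.DataFrame,
    checkups: pd.DataFrame,
) -> set:
    """Apply the four cohort-inclusion criteria; return selected patient ids.

    A patient is kept iff they have (i) a hypertension claim (I10), (ii) a
    diabetes claim (E10–E14), (iii) strictly more than 30 total days of
    antihypertensive supply, and (iv) complete check-up data (TC, BMI, FPG,
    BP, smoke, family history all present at every check-up).
    """
    claims = _valid_claims(claims)
    codes = claims["icd10_code"]

    has_htn = set(claims.loc[codes.str.startswith("I10"), "patient_id"])
    has_dm = set(
        claims.loc[codes.str.match(r"^E1[0-4]"), "patient_id"]
    )
    supply = prescriptions.groupby("patient_id")["days_supply"].sum()
    enough_supply = set(supply.index[supply > 30])

    present = checkups[_CHECKUP_REQUIRED].notna().all(axis=1)
    complete = set(
        checkups.assign(_ok=present).groupby("patient_id")["_ok"].all().pipe(
            lambda s: s.index[s]
        )
    )
    return has_htn & has_dm & enough_supply & complete


# ---------------------------------------------------------------------------
# Visit-state construction


def _match_prescriptions(
    visits: pd.DataFrame, prescriptions: pd.DataFrame
) -> pd.DataFrame:
    """Attach to each visit the prescription whose supply window covers it.

    The covering window with the nearest (latest) start date wins.  Visits
    with no covering window get a missing action.
    """
    rx = prescriptions.copy()
    rx["start_date"] = pd.to_datetime(rx["start_date"])
    # merge_asof needs a global sort on the date key
    rx = rx.sort_values("start_date", kind="mergesort")
    rx["_end"] = rx["start_date"] + pd.to_timedelta(
        rx["days_supply"], unit="D"
    )

    label_map = {
        lab: encode_action(parse_drug_classes(lab)).action_id
        for lab in rx["drug_classes"].astype(str).unique()
    }
    rx["_action_id"] = rx["drug_classes"].astype(str).map(label_map)

    visits = visits.sort_values("date", kind="mergesort")
    merged = pd.merge_asof(
        visits,
        rx[["patient_id", "start_date", "_end", "_action_id", "days_supply"]],
        left_on="date",
        right_on="start_date",
        by="patient_id",
        direction="backward",
    )
    covered = merged["start_date"].notna() & (merged["date"] < merged["_end"])
    merged.loc[~covered, ["_action_id", "days_supply"]] = np.nan

    # The nearest-start window may have lapsed while an earlier one still
    # covers (overlapping supplies); resolve those rows individually.
    needs_scan = (~covered) & merged["patient_id"].isin(rx["patient_id"])
    if needs_scan.any():
        rx_by_pid = dict(tuple(rx.groupby("patient_id")))
        for i in merged.index[needs_scan]:
            pid = merged.at[i, "patient_id"]
            date = merged.at[i, "date"]
            cand = rx_by_pid.get(pid)
            if cand is None:
                continue
            cover = cand[(cand["start_date"] <= date) & (date < cand["_end"])]
            if len(cover):
                best = cover.iloc[-1]  # latest start = nearest
                merged.at[i, "_action_id"] = best["_action_id"]
                merged.at[i, "days_supply"] = best["days_supply"]
    return merged.drop(columns=["start_date", "_end"]).rename(
        columns={"_action_id": "action_id"}
    )


def build_visit_states(
    checkups: pd.DataFrame,
    claims: pd.DataFrame,
    prescriptions: pd.DataFrame,
    patient_ids: set | None = None,
) -> pd.DataFrame:
    """Encode every check-up into a state index and a prescribed action.

    Returns a time-ordered table with one row per check-up:
    ``patient_id, date, state_index``, the five component columns, and a
    nullable ``action_id``/``days_supply`` from the covering prescription.
    Diabetes onset is the date of the patient's earliest E10–E14 claim;
    complication status is a prefix scan over I11/I12/I13 claim dates.
    """
    checkups = checkups.copy()
    checkups["date"] = pd.to_datetime(checkups["date"])
    if patient_ids is not None:
        checkups = checkups[checkups["patient_id"].isin(patient_ids)]

    claims = _valid_claims(claims)
    claims = claims.copy()
    claims["date"] = pd.to_datetime(claims["date"])

    codes = claims["icd10_code"]
    onset = (
        claims[codes.str.match(r"^E1[0-4]")]
        .groupby("patient_id")["date"]
        .min()
        .rename("onset_date")
    )
    first_comp = (
        claims[codes.str.startswith(COMPLICATION_CODES)]
        .groupby("patient_id")["date"]
        .min()
        .rename("first_complication_date")
    )

    visits = checkups.merge(onset, on="patient_id", how="left").merge(
        first_comp, on="patient_id", how="left"
    )
    if visits["onset_date"].isna().any():
        missing = visits.loc[visits["onset_date"].isna(), "patient_id"]
        raise ConfigurationError(
            "no diabetes (E10–E14) claim for patient(s) "
            f"{sorted(set(missing))[:5]}; run select_cohort first"
        )

    period_years = (
        (visits["date"] - visits["onset_date"]).dt.days / 365.25
    ).clip(lower=0.0)

    visits["complications"] = (
        visits["first_complication_date"].notna()
        & (visits["first_complication_date"] <= visits["date"])
    ).astype(np.int64)
    visits["age_flag"] = discretize_age(visits["age_years"].to_numpy())
    visits["period_level"] = discretize_period(period_years.to_numpy())
    visits["bp_level"] = discretize_bp(
        visits["systolic_bp"].to_numpy(), visits["diastolic_bp"].to_numpy()
    )
    visits["bmi_level"] = discretize_bmi(visits["bmi"].to_numpy())
    visits["state_index"] = (
        visits["complications"] * 54
        + visits["age_flag"] * 27
        + visits["period_level"] * 9
        + visits["bp_level"] * 3
        + visits["bmi_level"]
    )

    cols = [
        "patient_id",
        "date",
        "state_index",
        "complications",
        "age_flag",
        "period_level",
        "bp_level",
        "bmi_level",
    ]
    out = _match_prescriptions(visits[cols], prescriptions)
    out = out.sort_values(["patient_id", "date"], kind="mergesort")
    out["action_id"] = out["action_id"].astype("Int64")

    n_single = int(
        (out.groupby("patient_id")["date"].transform("size") < 2).sum()
    )
    if n_single:
        logger.info(
            "%d visit(s) belong to patients with fewer than 2 visits; "
            "they contribute no transitions", n_single,
        )
    return out.reset_index(drop=True)
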