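"""Schema-validated CSV readers/writers and the end-to-end pipeline.

The raw cohort is exchanged as three flat CSV tables (comma-separated,
UTF-8, header row, ISO-8601 dates):

``checkups.csv``
    patient_id, date, systolic_bp, diastolic_bp, bmi, fpg, tc, smoke,
    family_history, age_years
``claims.csv``
    patient_id, date, icd10_code
``prescriptions.csv``
    patient_id, start_date, days_supply, drug_classes (e.g. "ARB+CCB")

``run_pipeline`` chains simulate -> build-cohort -> train (Q-learning and
the MDP baseline) -> evaluate, writes the report CSVs plus a manifest, and
is byte-for-byte reproducible under a fixed config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_builder, evaluation, policy_learning, synthetic_cohort
from .errors import ConfigurationError, SchemaError
from .policy_learning import LearnParams, Policy, QTable
from .reward_model import (
    RewardConfig,
    reward_config_from_dict,
    reward_config_to_dict,
)
from .synthetic_cohort import SimulationConfig

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Table schemas


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[str, ...]
    date_columns: tuple[str, ...] = ()
    positive_columns: tuple[str, ...] = ()


CHECKUP_SCHEMA = TableSchema(
    "checkups",
    (
        "patient_id",
        "date",
        "systolic_bp",
        "diastolic_bp",
        "bmi",
        "fpg",
        "tc",
        "smoke",
        "family_history",
        "age_years",
    ),
    date_columns=("date",),
    positive_columns=("systolic_bp", "diastolic_bp", "bmi", "age_years"),
)
CLAIM_SCHEMA = TableSchema(
    "claims", ("patient_id", "date", "icd10_code"), date_columns=("date",)
)
PRESCRIPTION_SCHEMA = TableSchema(
    "prescriptions",
    ("patient_id", "start_date", "days_supply", "drug_classes"),
    date_columns=("start_date",),
    positive_columns=("days_supply",),
)
VISIT_SCHEMA = TableSchema(
    "visits",
    (
        "patient_id",
        "date",
        "state_index",
        "complications",
        "age_flag",
        "period_level",
        "bp_level",
        "bmi_level",
        "action_id",
        "days_supply",
    ),
    date_columns=("date",),
)

RAW_SCHEMAS = {
    "checkups": CHECKUP_SCHEMA,
    "claims": CLAIM_SCHEMA,
    "prescriptions": PRESCRIPTION_SCHEMA,
}


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate one CSV table; errors name rows and columns."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing} for table "
            f"'{schema.name}'"
        )
    for col in schema.date_columns:
        try:
            df[col] = pd.to_datetime(df[col], format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise SchemaError(
                f"{path}: unparseable date in column '{col}': {exc}"
            ) from exc
    for col in schema.positive_columns:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.notna() & (values <= 0)]
        if len(bad):
            raise SchemaError(
                f"{path}: non-positive value(s) in column '{col}' at "
                f"row(s) {list(bad[:5])}"
            )
    return df[list(schema.columns)]


def write_table(df: pd.DataFrame, path: str | Path, schema: TableSchema) -> None:
    """Write one table with ISO dates and the schema's column order."""
    path = Path(path)
    out = df.copy()
    missing = [c for c in schema.columns if c not in out.columns]
    if missing:
        raise SchemaError(
            f"cannot write table '{schema.name}': missing {missing}"
        )
    for col in schema.date_columns:
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out[list(schema.columns)].to_csv(path, index=False)


def write_raw_tables(dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the three raw tables plus a JSON sidecar with config + hash."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("checkups", dataset.checkups),
        ("claims", dataset.claims),
        ("prescriptions", dataset.prescriptions),
    ):
        paths[name] = out_dir / f"{name}.csv"
        write_table(df, paths[name], RAW_SCHEMAS[name])
    sidecar = {
        "config": dataclasses.asdict(dataset.config),
        "ground_truth_hash": dataset.mdp.tensor_hash(),
    }
    (out_dir / "simulation.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )
    return paths


def read_raw_tables(in_dir: str | Path):
    in_dir = Path(in_dir)
    return (
        read_table(in_dir / "checkups.csv", CHECKUP_SCHEMA),
        read_table(in_dir / "claims.csv", CLAIM_SCHEMA),
        read_table(in_dir / "prescriptions.csv", PRESCRIPTION_SCHEMA),
    )


# ---------------------------------------------------------------------------
# Q-table / policy serialization


def write_qtable(q: QTable, path: str | Path) -> None:
    s, a = np.divmod(np.arange(q.n_states * q.n_actions), q.n_actions)
    pd.DataFrame(
        {
            "state_index": s,
            "action_id": a + 1,
            "q_value": q.values.reshape(-1),
            "visits": q.counts.reshape(-1),
        }
    ).to_csv(path, index=False)


def read_qtable(path: str | Path) -> QTable:
    df = pd.read_csv(path)
    n_states = int(df["state_index"].max()) + 1
    n_actions = int(df["action_id"].max())
    q = QTable.zeros(n_states, n_actions)
    q.values[df["state_index"], df["action_id"] - 1] = df["q_value"]
    q.counts[df["state_index"], df["action_id"] - 1] = df["visits"]
    return q


def write_policy(policy: Policy, path: str | Path) -> None:
    pd.DataFrame(
        {
            "state_index": np.arange(policy.n_states),
            "recommended_action": policy.action_by_state,
        }
    ).to_csv(path, index=False)


def read_policy(path: str | Path) -> Policy:
    df = pd.read_csv(path)
    n_states = int(df["state_index"].max()) + 1
    actions = np.zeros(n_states, dtype=np.int64)
    actions[df["state_index"]] = df["recommended_action"]
    return Policy(actions)


# ---------------------------------------------------------------------------
# Pipeline configuration


@dataclass
class PipelineConfig:
    """One config object driving the full simulate-to-evaluate pipeline.

    The global ``seed`` fans out to the stages by fixed offsets so a
    single knob reproduces the whole run.
    """

    seed: int = 0
    simulation: SimulationConfig = None
    reward: RewardConfig = field(default_factory=RewardConfig)
    learning: LearnParams = None
    denominator_mode: str = "paper"
    bp_outcome: str = "final"  # or "mean"

    def __post_init__(self) -> None:
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed + 1)
        if self.learning is None:
            self.learning = LearnParams(seed=self.seed + 2)
        if self.bp_outcome not in ("final", "mean"):
            raise ConfigurationError(
                f"unknown bp_outcome: {self.bp_outcome!r}"
            )
        if self.denominator_mode not in ("paper", "supported"):
            raise ConfigurationError(
                f"unknown denominator_mode: {self.denominator_mode!r}"
            )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "simulation": dataclasses.asdict(self.simulation),
            "reward": reward_config_to_dict(self.reward),
            "learning": {
                **dataclasses.asdict(self.learning),
            },
            "denominator_mode": self.denominator_mode,
            "bp_outcome": self.bp_outcome,
        }


def pipeline_config_from_dict(data: dict) -> PipelineConfig:
    kwargs: dict = {"seed": int(data.get("seed", 0))}
    if "simulation" in data:
        sim = dict(data["simulation"])
        if "adherence_range" in sim:
            sim["adherence_range"] = tuple(sim["adherence_range"])
        kwargs["simulation"] = SimulationConfig(**sim)
    if "reward" in data:
        kwargs["reward"] = reward_config_from_dict(data["reward"])
    if "learning" in data:
        kwargs["learning"] = LearnParams(**data["learning"])
    for key in ("denominator_mode", "bp_outcome"):
        if key in data:
            kwargs[key] = data[key]
    return PipelineConfig(**kwargs)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    text = path.read_text()
    data = (
        json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    )
    return pipeline_config_from_dict(data or {})


# ---------------------------------------------------------------------------
# End-to-end pipeline


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Simulate, build the cohort, train both learners, evaluate, report.

    Writes raw tables, the encoded visit table, Q-table/policy CSVs, the
    evaluation reports (concordance.csv, mpr_summary.csv,
    bucket_curves.csv, recommendation_mix.csv) and ``manifest.json``.
    Returns the manifest.  On stage failure the partially written output
    directory is removed (if this call created it) and a
    :class:`PipelineError` naming the stage is raised.
    """
    out_dir = Path(out_dir)
    created = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        dataset = synthetic_cohort.simulate_dataset(config.simulation)
        write_raw_tables(dataset, out_dir / "raw")

        stage = "build-cohort"
        ids = cohort_builder.select_cohort(
            dataset.claims, dataset.prescriptions, dataset.checkups
        )
        visits = cohort_builder.build_visit_states(
            dataset.checkups, dataset.claims, dataset.prescriptions, ids
        )
        write_table(visits, out_dir / "visits.csv", VISIT_SCHEMA)

        stage = "train"
        samples = policy_learning.extract_transitions(visits, config.reward)
        q = policy_learning.fit_q_learning(
            samples,
            config.learning,
            n_states=cohort_builder.N_STATES,
            n_actions=cohort_builder.N_ACTIONS,
        )
        model_policy = policy_learning.greedy_policy(
            q,
            config.learning.restrict_to_observed,
            config.learning.min_support,
        )
        write_qtable(q, out_dir / "qtable.csv")
        write_policy(model_policy, out_dir / "policy.csv")

        P_hat, R_hat, counts = policy_learning.estimate_transition_model(
            samples
        )
        vi = policy_learning.value_iteration(
            P_hat, R_hat, gamma=config.learning.gamma
        )
        mdp_policy = Policy(vi.policy.action_by_state.copy())
        if config.learning.restrict_to_observed:
            mdp_policy.action_by_state[counts.sum(axis=1) == 0] = 0
        write_policy(mdp_policy, out_dir / "policy_mdp.csv")

        stage = "evaluate"
        doctors = evaluation.doctor_policy(visits)
        planted = synthetic_cohort.tier_appropriate_policy()
        concordance_rows = []
        for name, pol in (
            ("q_learning", model_policy),
            ("mdp_baseline", mdp_policy),
        ):
            for ref_name, ref in (
                ("doctor", doctors.as_policy),
                ("planted_optimal", planted),
            ):
                matched, rate = evaluation.concordance_rate(
                    pol, ref, config.denominator_mode
                )
                concordance_rows.append(
                    {
                        "model": name,
                        "reference": ref_name,
                        "matched_states": matched,
                        "concordance_rate": rate,
                    }
                )
        concordance = pd.DataFrame(concordance_rows)
        concordance.to_csv(out_dir / "concordance.csv", index=False)

        records = evaluation.model_adherence_records(
            visits,
            model_policy,
            episode_days=config.simulation.visit_interval_days,
        )
        summary = evaluation.mpr_summary(records)
        summary.reset_index().to_csv(out_dir / "mpr_summary.csv", index=False)

        pc = evaluation.patient_concordance(visits, model_policy)
        at_risk = evaluation.baseline_complication_free(visits)
        comp_curve = evaluation.bucket_outcomes(
            pc.loc[pc.index.intersection(at_risk)],
            evaluation.complication_occurrence(dataset.claims, visits),
        )
        bp_outcome = (
            evaluation.final_bp_level(visits)
            if config.bp_outcome == "final"
            else evaluation.mean_bp_level(visits)
        )
        bp_curve = evaluation.bucket_outcomes(pc, bp_outcome)
        curves = pd.concat(
            [
                comp_curve.as_frame().assign(outcome="complication_occurrence"),
                bp_curve.as_frame().assign(outcome="bp_level"),
            ],
            ignore_index=True,
        )
        curves.to_csv(out_dir / "bucket_curves.csv", index=False)

        mix = evaluation.recommendation_distributions(model_policy, visits)
        mix_frame = mix.tier_share_by_component.reset_index()
        mix_frame.to_csv(out_dir / "recommendation_mix.csv", index=False)
        mix.action_share.reset_index().to_csv(
            out_dir / "recommendation_actions.csv", index=False
        )

        manifest = {
            "config": config.to_dict(),
            "config_hash": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True).encode()
            ).hexdigest(),
            "ground_truth_hash": dataset.mdp.tensor_hash(),
            "n_patients": int(dataset.config.n_patients),
            "n_visits": int(len(visits)),
            "n_transitions": int(len(samples)),
            "q_learning_converged": bool(q.converged),
            "q_learning_sweeps": int(q.n_sweeps),
            "concordance": {
                f"{r['model']}_vs_{r['reference']}": r["concordance_rate"]
                for r in concordance_rows
            },
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        return manifest
    except Exception as exc:
        if created:
            shutil.rmtree(out_dir, ignore_errors=True)
        raise PipelineError(f"pipeline stage '{stage}' failed: {exc}") from exc
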