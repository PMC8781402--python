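"""QALY-based reward for a treatment action and its resulting state.

The utility of the state reached after treatment is expressed as one QALY
degraded by five multiplicative utility decrements — one per state
component (complications, age, diabetes duration, blood pressure, BMI):

    U(s') = (1 - d_comp)(1 - d_age)(1 - d_period)(1 - d_bp)(1 - d_bmi)

and the reward of taking action ``a`` and landing in ``s'`` is

    R(a, s') = R_WTP * U(s') - C_MED(a)

where ``R_WTP`` is the willingness-to-pay for one QALY and ``C_MED`` the
medication cost of the regimen, in the same units.  The default
willingness-to-pay is 1.0, i.e. rewards live on the QALY scale and costs
are expressed as fractions of one QALY; the greedy policy is invariant to
jointly rescaling both (see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .cohort_builder import (
    ACTIONS,
    Action,
    N_ACTIONS,
    N_STATES,
    StateVector,
    decode_state,
)
from .errors import ConfigurationError


@dataclass(frozen=True)
class DecrementTable:
    """Utility decrement per state-component level.

    Each tuple is indexed by the component's coded level.  Note the age
    entry is indexed by the *flag* (1 = younger than 55, decrement 0.08;
    0 = 55 or older, decrement 0.129).
    """

    complications: tuple[float, float] = (0.010, 0.248)
    age: tuple[float, float] = (0.129, 0.08)
    period: tuple[float, float, float] = (0.078, 0.085, 0.112)
    bp: tuple[float, float, float] = (0.034, 0.125, 0.278)
    bmi: tuple[float, float, float] = (0.028, 0.07, 0.172)

    def __post_init__(self) -> None:
        for name in ("complications", "age", "period", "bp", "bmi"):
            for d in getattr(self, name):
                if not 0.0 <= d < 1.0:
                    raise ConfigurationError(
                        f"decrement {name}={d} outside [0, 1)"
                    )


DEFAULT_DECREMENTS = DecrementTable()


def _default_med_cost() -> dict[int, float]:
    # Cost ladder by therapy tier: 0 / 0.01 / 0.02 QALY-equivalents for
    # mono/dual/triple.  Imposes mild parsimony pressure; overridable.
    return {a.action_id: 0.01 * (a.tier - 1) for a in ACTIONS}


@dataclass(frozen=True)
class RewardConfig:
    """Willingness-to-pay, per-action medication cost, and decrements."""

    rwtp: float = 1.0
    med_cost: Mapping[int, float] = field(default_factory=_default_med_cost)
    decrements: DecrementTable = DEFAULT_DECREMENTS

    def __post_init__(self) -> None:
        if not self.rwtp > 0:
            raise ConfigurationError("rwtp must be positive")
        for aid, cost in self.med_cost.items():
            if cost < 0:
                raise ConfigurationError(
                    f"medication cost for action {aid} is negative"
                )

    def cost_of(self, action_id: int) -> float:
        try:
            return float(self.med_cost[action_id])
        except KeyError as exc:
            raise ConfigurationError(
                f"no medication cost configured for action {action_id}"
            ) from exc


def qaly_multiplier(
    state: StateVector, decrements: DecrementTable = DEFAULT_DECREMENTS
) -> float:
    """Product of the five (1 - decrement) factors for ``state``."""
    d = decrements
    return (
        (1.0 - d.complications[state.complications])
        * (1.0 - d.age[state.age_flag])
        * (1.0 - d.period[state.period_level])
        * (1.0 - d.bp[state.bp_level])
        * (1.0 - d.bmi[state.bmi_level])
    )


def multiplier_vector(
    decrements: DecrementTable = DEFAULT_DECREMENTS,
) -> np.ndarray:
    """QALY multiplier of every state, indexed by state index (shape 108)."""
    return np.array(
        [qaly_multiplier(decode_state(i), decrements) for i in range(N_STATES)]
    )


def reward(
    action: Action | int,
    next_state: StateVector,
    config: RewardConfig = RewardConfig(),
) -> float:
    """R(a, s') = rwtp * U(s') - cost(a)."""
    action_id = action.action_id if isinstance(action, Action) else int(action)
    return (
        config.rwtp * qaly_multiplier(next_state, config.decrements)
        - config.cost_of(action_id)
    )


def reward_matrix(config: RewardConfig = RewardConfig()) -> np.ndarray:
    """Reward of every (next-state, action) pair, shape (108, 14).

    Entry ``[s', a-1]`` is the reward of reaching state ``s'`` under
    action id ``a``.
    """
    mult = multiplier_vector(config.decrements)
    costs = np.array([config.cost_of(a.action_id) for a in ACTIONS])
    return config.rwtp * mult[:, None] - costs[None, :]


# ---------------------------------------------------------------------------
# Config (de)serialization


def reward_config_from_dict(data: dict) -> RewardConfig:
    kwargs: dict = {}
    if "rwtp" in data:
        kwargs["rwtp"] = float(data["rwtp"])
    if "med_cost" in data:
        kwargs["med_cost"] = {
            int(k): float(v) for k, v in data["med_cost"].items()
        }
    if "decrements" in data:
        dec = {k: tuple(v) for k, v in data["decrements"].items()}
        kwargs["decrements"] = DecrementTable(**dec)
    return RewardConfig(**kwargs)


def load_reward_config(path: str | Path) -> RewardConfig:
    """Load a :class:`RewardConfig` from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = (
        json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    )
    return reward_config_from_dict(data or {})


def reward_config_to_dict(config: RewardConfig) -> dict:
    return {
        "rwtp": config.rwtp,
        "med_cost": {int(k): float(v) for k, v in config.med_cost.items()},
        "decrements": {
            "complications": list(config.decrements.complications),
            "age": list(config.decrements.age),
            "period": list(config.decrements.period),
            "bp": list(config.decrements.bp),
            "bmi": list(config.decrements.bmi),
        },
    }
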