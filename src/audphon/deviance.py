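"""Normative individual deviance analysis.

Each patient is compared against a norm built from the control group:
the worst-performing 5% of controls are removed (trimmed norm), all
participants are z-scored against the trimmed norm's mean and SD, and a
participant is flagged deviant when their z-score exceeds 1.65 SD in the
task's worse direction (higher RTD threshold = worse; shallower
identification slope = worse). Per-task deviance proportions, the union
(deviant on at least one task) and the overlap between tasks are
reported for the patient group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

Direction = Literal["higher_is_worse", "lower_is_worse"]
TrimRule = Literal["ceil", "floor", "round"]


class DegenerateNormError(ValueError):
    """Trimmed control norm has zero spread; z-scores are undefined."""


class DevianceConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    trim_fraction: float = Field(default=0.05, ge=0, lt=0.5)
    deviance_sd: float = Field(default=1.65, gt=0)
    trim_count_rule: TrimRule = "ceil"
    worse_direction: dict[str, Direction] = Field(
        default_factory=lambda: {
            "rtd_log_threshold": "higher_is_worse",
            "id_slope": "lower_is_worse",
        }
    )


def _trim_count(n: int, fraction: float, rule: TrimRule) -> int:
    raw = fraction * n
    if rule == "ceil":
        return math.ceil(raw)
    if rule == "floor":
        return math.floor(raw)
    return round(raw)


def trim_controls(
    control_scores: Sequence[float],
    config: Optional[DevianceConfig] = None,
    task_direction: Direction = "higher_is_worse",
) -> np.ndarray:
    """Remove the worst-performing trim_fraction of controls.

    "Worst" means the largest scores when higher is worse and the
    smallest when lower is worse. With the default ceil rule and 5%,
    n = 23 controls lose 2 members (trimmed n = 21).
    """
    config = config or DevianceConfig()
    scores = np.asarray(control_scores, dtype=float)
    if scores.size < 3:
        raise ValueError("need at least 3 control scores to build a norm")
    k = _trim_count(scores.size, config.trim_fraction, config.trim_count_rule)
    if k == 0:
        return scores.copy()
    order = np.argsort(scores, kind="stable")
    keep = order[:-k] if task_direction == "higher_is_worse" else order[k:]
    return scores[np.sort(keep)]


def zscore_by_norm(
    all_scores: Sequence[float], trimmed_controls: Sequence[float]
) -> np.ndarray:
    """Standardize scores against the trimmed-norm mean and sample SD
    (ddof = 1)."""
    trimmed = np.asarray(trimmed_controls, dtype=float)
    mean = trimmed.mean()
    sd = trimmed.std(ddof=1)
    if not sd > 0:
        raise DegenerateNormError("trimmed control norm has zero SD")
    return (np.asarray(all_scores, dtype=float) - mean) / sd


def classify_deviant(
    z: Sequence[float],
    config: Optional[DevianceConfig] = None,
    task_direction: Direction = "higher_is_worse",
) -> np.ndarray:
    """Deviance flags: strictly beyond +/-1.65 SD in the worse direction
    (a z of exactly 1.65 is not deviant — the score must exceed it)."""
    config = config or DevianceConfig()
    z = np.asarray(z, dtype=float)
    if task_direction == "higher_is_worse":
        return z > config.deviance_sd
    return z < -config.deviance_sd


@dataclass
class TaskDeviance:
    task: str
    direction: Direction
    trimmed_n: int
    norm_mean: float
    norm_sd: float
    z_scores: pd.Series  # indexed by participant_id, valid scores only
    deviant: pd.Series   # boolean, same index
    n_patients: int
    n_patients_deviant: int

    @property
    def patient_proportion(self) -> float:
        return self.n_patients_deviant / self.n_patients


@dataclass
class DevianceReport:
    per_task: dict[str, TaskDeviance]
    union_n: int               # patients with >= 1 valid task score
    union_deviant: int         # of those, deviant on >= 1 task
    both_n: int                # patients with valid scores on both tasks
    deviant_on_both: int
    deviant_on_exactly_one: int

    @property
    def union_proportion(self) -> float:
        return self.union_deviant / self.union_n

    def summary(self) -> dict:
        return {
            "per_task": {
                t: {
                    "trimmed_n": d.trimmed_n,
                    "norm_mean": d.norm_mean,
                    "norm_sd": d.norm_sd,
                    "n_patients": d.n_patients,
                    "n_patients_deviant": d.n_patients_deviant,
                    "proportion_deviant": d.patient_proportion,
                }
                for t, d in self.per_task.items()
            },
            "union": {
                "n": self.union_n,
                "deviant": self.union_deviant,
                "proportion": self.union_proportion,
            },
            "overlap": {
                "both_valid_n": self.both_n,
                "deviant_on_both": self.deviant_on_both,
                "deviant_on_exactly_one": self.deviant_on_exactly_one,
            },
        }


def deviance_report(
    scores: pd.DataFrame,
    config: Optional[DevianceConfig] = None,
    patient_group: str = "aphasia",
    control_group: str = "control",
) -> DevianceReport:
    """Run the full deviance analysis over a long-format score table.

    ``scores`` columns: participant_id, group, task, score, valid.
    Invalid or missing scores are dropped per task; the trimmed norm is
    built from the controls with valid scores on that task.
    """
    config = config or DevianceConfig()
    required = {"participant_id", "group", "task", "score", "valid"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    valid = scores[scores["valid"] & scores["score"].notna()]
    if valid.empty:
        raise ValueError("no valid scores to analyze")

    per_task: dict[str, TaskDeviance] = {}
    patient_flags: dict[str, pd.Series] = {}
    for task, sub in valid.groupby("task"):
        direction = config.worse_direction.get(task, "higher_is_worse")
        controls = sub[sub["group"] == control_group]
        patients = sub[sub["group"] == patient_group]
        if controls.empty or patients.empty:
            continue
        trimmed = trim_controls(controls["score"].to_numpy(), config, direction)
        z = zscore_by_norm(sub["score"].to_numpy(), trimmed)
        flags = classify_deviant(z, config, direction)
        zs = pd.Series(z, index=sub["participant_id"].to_numpy())
        fl = pd.Series(flags, index=sub["participant_id"].to_numpy())
        pat_fl = fl.loc[patients["participant_id"]]
        per_task[task] = TaskDeviance(
            task=task,
            direction=direction,
            trimmed_n=len(trimmed),
            norm_mean=float(np.mean(trimmed)),
            norm_sd=float(np.std(trimmed, ddof=1)),
            z_scores=zs,
            deviant=fl,
            n_patients=len(pat_fl),
            n_patients_deviant=int(pat_fl.sum()),
        )
        patient_flags[task] = pat_fl

    if not per_task:
        raise ValueError("no task had both control and patient scores")

    all_flags = pd.DataFrame(patient_flags)  # NaN where a task is missing
    union_n = int((all_flags.notna().any(axis=1)).sum())
    union_deviant = int((all_flags == True).any(axis=1).sum())  # noqa: E712
    both = all_flags.dropna()
    deviant_counts = both.sum(axis=1)
    return DevianceReport(
        per_task=per_task,
        union_n=union_n,
        union_deviant=union_deviant,
        both_n=len(both),
        deviant_on_both=int((deviant_counts == all_flags.shape[1]).sum()),
        deviant_on_exactly_one=int((deviant_counts == 1).sum()),
    )
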