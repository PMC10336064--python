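"""Synthetic observers for the auditory-phonemic test battery.

This module generates cohorts of simulated participants (age-matched
controls and individuals with post-stroke aphasia, IWA) whose task
responses have the statistical structure the downstream analyses assume:

* a 3AFC rise-time discrimination (RTD) observer with a monotone
  psychometric function on the log rise-time axis, parameterised by the
  rise time at which the proportion correct equals 70.7% (the level the
  two-down/one-up staircase converges to);
* a 2AFC phoneme-identification observer: a four-parameter sigmoid
  (midpoint, width, guess rate, lapse rate) on the 10-step /bA/-/dA/
  continuum;
* hearing (Fletcher index, dB HL) and cognition (standardised composite)
  covariates, drawn group-specifically;
* phonological outcomes (ScreeLing phonology subtest, 0-24; phonological
  word fluency count) linearly linked to the log RTD threshold.

Everything is driven by a single integer seed; identical configuration
and seed give identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

RTD_REFERENCE_MS = 15.0
#: 3AFC chance level
GUESS_3AFC = 1.0 / 3.0
#: target proportion correct of the two-down/one-up staircase
P_TARGET = 0.707
#: sigmoid height at the 70.7%-correct point: (0.707 - 1/3) / (2/3)
_C_TARGET = (P_TARGET - GUESS_3AFC) / (1.0 - GUESS_3AFC)
#: feasibility bound: log(x707/ref)/width must exceed log(1/(1-c))
_MIN_U_OVER_W = math.log(1.0 / (1.0 - _C_TARGET))

Group = Literal["control", "aphasia"]


class ConfigurationError(ValueError):
    """Raised when a cohort or observer configuration is invalid."""


@dataclass(frozen=True)
class ObserverProfile:
    """Latent parameters of one simulated participant.

    ``rtd_x707_ms`` is the deviant rise time (ms) at which the observer's
    3AFC proportion correct equals 0.707; ``rtd_width_log`` is the
    psychometric width on the natural-log rise-time axis. The
    identification sigmoid lives on continuum-step units (1..10).
    """

    participant_id: str
    group: Group
    rtd_x707_ms: float
    rtd_width_log: float
    id_midpoint: float
    id_width: float
    id_guess: float
    id_lapse: float
    hearing_fletcher_db: float
    cognition_z: float
    phonology_screeling: float
    fluency_count: int
    rtd_completed: bool = True
    id_completed: bool = True

    def __post_init__(self) -> None:
        if self.group not in ("control", "aphasia"):
            raise ConfigurationError(f"unknown group label {self.group!r}")
        if not self.rtd_x707_ms > RTD_REFERENCE_MS:
            raise ConfigurationError(
                f"rtd_x707_ms must exceed the {RTD_REFERENCE_MS} ms reference, "
                f"got {self.rtd_x707_ms}"
            )
        if self.rtd_width_log <= 0 or self.id_width <= 0:
            raise ConfigurationError("psychometric widths must be positive")
        if not (0 <= self.id_guess <= 0.89):
            raise ConfigurationError("id_guess outside [0, 0.89]")
        if not (0 <= self.id_lapse <= 0.1):
            raise ConfigurationError("id_lapse outside [0, 0.1]")
        if self.id_guess + self.id_lapse >= 1:
            raise ConfigurationError("id_guess + id_lapse must be < 1")
        if not (0 <= self.phonology_screeling <= 24):
            raise ConfigurationError("phonology_screeling outside [0, 24]")
        if self.fluency_count < 0:
            raise ConfigurationError("fluency_count must be non-negative")
        u707 = math.log(self.rtd_x707_ms / RTD_REFERENCE_MS)
        if u707 / self.rtd_width_log <= _MIN_U_OVER_W:
            raise ConfigurationError(
                "rtd_width_log too large for rtd_x707_ms: the anchored sigmoid "
                f"requires log(x707/ref)/width > {_MIN_U_OVER_W:.4f}"
            )


class GroupParams(BaseModel):
    """Generating distributions for one group."""

    model_config = ConfigDict(extra="forbid")

    mean_log_x707: float
    sd_log_x707: float = Field(gt=0)
    mean_rtd_width_log: float = Field(default=0.35, gt=0)
    sd_rtd_width_log: float = Field(default=0.10, gt=0)
    mean_id_midpoint: float = 5.5
    sd_id_midpoint: float = Field(default=0.4, gt=0)
    mean_id_width: float = Field(gt=0)
    sd_id_width: float = Field(gt=0)
    guess_range: tuple[float, float] = (0.0, 0.08)
    lapse_range: tuple[float, float] = (0.0, 0.04)
    hearing_mean_db: float = 32.0
    hearing_sd_db: float = Field(default=9.0, gt=0)
    cognition_mean: float = 0.0
    cognition_sd: float = Field(default=1.0, gt=0)
    p_rtd_incomplete: float = Field(default=0.0, ge=0, le=1)
    p_id_incomplete: float = Field(default=0.0, ge=0, le=1)

    @model_validator(mode="after")
    def _check_ranges(self) -> "GroupParams":
        g0, g1 = self.guess_range
        l0, l1 = self.lapse_range
        if not (0 <= g0 <= g1 <= 0.89):
            raise ValueError("guess_range must lie within [0, 0.89]")
        if not (0 <= l0 <= l1 <= 0.1):
            raise ValueError("lapse_range must lie within [0, 0.1]")
        return self


def _default_control() -> GroupParams:
    return GroupParams(
        mean_log_x707=math.log(40.0), sd_log_x707=0.35,
        mean_id_width=1.2, sd_id_width=0.15,
    )


def _default_aphasia() -> GroupParams:
    return GroupParams(
        mean_log_x707=math.log(80.0), sd_log_x707=0.65,
        mean_id_width=3.0, sd_id_width=1.2,
        guess_range=(0.0, 0.30), lapse_range=(0.0, 0.10),
        cognition_mean=-1.5, cognition_sd=1.0,
        p_rtd_incomplete=6 / 29, p_id_incomplete=3 / 29,
    )


class CohortConfig(BaseModel):
    """Full generating model for a synthetic cohort.

    The default group sizes (23 controls, 29 IWA) and the default
    phonology link slope on the log RTD threshold (-2.70 ScreeLing
    points per log-ms) match the study design this pipeline reproduces.
    """

    model_config = ConfigDict(extra="forbid")

    n_control: int = Field(default=23, ge=1)
    n_aphasia: int = Field(default=29, ge=1)
    control: GroupParams = Field(default_factory=_default_control)
    aphasia: GroupParams = Field(default_factory=_default_aphasia)
    phonology_intercept: float = 32.0
    phonology_beta_logrtd: float = -2.70
    phonology_beta_hearing: float = 0.0
    phonology_beta_cognition: float = 0.5
    phonology_noise_sd: float = Field(default=2.5, gt=0)
    fluency_intercept: float = 18.0
    fluency_beta_logrtd: float = 0.0
    fluency_noise_sd: float = Field(default=5.0, gt=0)
    seed: int = 0

    def group_params(self, group: str) -> GroupParams:
        if group == "control":
            return self.control
        if group == "aphasia":
            return self.aphasia
        raise ConfigurationError(f"unknown group label {group!r}")


def make_observer(
    group: Group,
    config: CohortConfig,
    draw: np.random.Generator,
    participant_id: str = "sim-000",
) -> ObserverProfile:
    """Draw one observer from the group's generating distributions.

    The latent log RTD threshold is normal; the phonology score is the
    linear predictor intercept + beta_logrtd*log(x707) +
    beta_hearing*hearing + beta_cognition*cognition plus Gaussian noise,
    clipped to the [0, 24] range of the ScreeLing phonology subtest.
    Draws that would violate observer invariants (x707 at or below the
    15 ms reference; psychometric width infeasible for the anchored
    sigmoid) are clipped into the valid region.
    """
    gp = config.group_params(group)
    log_x707 = draw.normal(gp.mean_log_x707, gp.sd_log_x707)
    # keep the 70.7% point at least one ladder quantum above the reference
    log_x707 = max(log_x707, math.log(16.0))
    x707 = math.exp(log_x707)

    u707 = log_x707 - math.log(RTD_REFERENCE_MS)
    w_max = 0.95 * u707 / _MIN_U_OVER_W
    rtd_width = float(np.clip(draw.normal(gp.mean_rtd_width_log, gp.sd_rtd_width_log),
                              0.02, w_max))

    id_mid = draw.normal(gp.mean_id_midpoint, gp.sd_id_midpoint)
    id_width = max(0.15, draw.normal(gp.mean_id_width, gp.sd_id_width))
    guess = draw.uniform(*gp.guess_range)
    lapse = draw.uniform(*gp.lapse_range)

    hearing = draw.normal(gp.hearing_mean_db, gp.hearing_sd_db)
    cognition = draw.normal(gp.cognition_mean, gp.cognition_sd)

    phon_mean = (config.phonology_intercept
                 + config.phonology_beta_logrtd * log_x707
                 + config.phonology_beta_hearing * hearing
                 + config.phonology_beta_cognition * cognition)
    phonology = float(np.clip(phon_mean + draw.normal(0.0, config.phonology_noise_sd),
                              0.0, 24.0))
    flu_mean = config.fluency_intercept + config.fluency_beta_logrtd * log_x707
    fluency = int(max(0, round(flu_mean + draw.normal(0.0, config.fluency_noise_sd))))

    rtd_done = bool(draw.random() >= gp.p_rtd_incomplete)
    id_done = bool(draw.random() >= gp.p_id_incomplete)

    return ObserverProfile(
        participant_id=participant_id,
        group=group,
        rtd_x707_ms=x707,
        rtd_width_log=rtd_width,
        id_midpoint=float(id_mid),
        id_width=float(id_width),
        id_guess=float(guess),
        id_lapse=float(lapse),
        hearing_fletcher_db=float(hearing),
        cognition_z=float(cognition),
        phonology_screeling=phonology,
        fluency_count=fluency,
        rtd_completed=rtd_done,
        id_completed=id_done,
    )


def p_correct_rtd(observer: ObserverProfile, deviant_rise_ms: float) -> float:
    """3AFC probability correct for a deviant of the given rise time.

    The model is p = 1/3 + (2/3) * F(u) with u = log(deviant/reference)
    and F a logistic sigmoid renormalised so that F(0) = 0 (a deviant
    identical to the 15 ms reference is at chance) and
    F(log(x707/reference)) = 0.5605, which puts p at exactly 0.707 at the
    observer's threshold parameter. Closed form:

        F(u) = (exp(u/w) - 1) / (exp(u/w) + K)

    with K > 0 solved from the 70.7% anchor.
    """
    if deviant_rise_ms < RTD_REFERENCE_MS:
        raise ValueError(
            f"deviant rise time {deviant_rise_ms} ms below the "
            f"{RTD_REFERENCE_MS} ms reference"
        )
    w = observer.rtd_width_log
    u = math.log(deviant_rise_ms / RTD_REFERENCE_MS)
    u707 = math.log(observer.rtd_x707_ms / RTD_REFERENCE_MS)
    q = math.exp(u707 / w)
    K = (q * (1.0 - _C_TARGET) - 1.0) / _C_TARGET  # > 0 by profile invariant
    eu = math.exp(u / w)
    F = (eu - 1.0) / (eu + K)
    return GUESS_3AFC + (1.0 - GUESS_3AFC) * F


def simulate_rtd_trial(
    observer: ObserverProfile, deviant_rise_ms: float, draw: np.random.Generator
) -> bool:
    """One Bernoulli 3AFC trial."""
    return bool(draw.random() < p_correct_rtd(observer, deviant_rise_ms))


def p_da(observer: ObserverProfile, step: float) -> float:
    """Probability of a /dA/ response at a continuum step (1..10).

    psi(x) = guess + (1 - guess - lapse) * S((x - midpoint)/width), with S
    the standard logistic.
    """
    if not (1 <= step <= 10):
        raise ValueError(f"continuum step {step} outside 1..10")
    from scipy.special import expit

    z = (step - observer.id_midpoint) / observer.id_width
    s = float(expit(z))
    return observer.id_guess + (1.0 - observer.id_guess - observer.id_lapse) * s


@dataclass(frozen=True)
class IdentificationData:
    """Per-step /dA/ response counts of the 2AFC identification task."""

    steps: tuple[int, ...]
    da_counts: tuple[int, ...]
    reps_per_step: int = 8

    def __post_init__(self) -> None:
        if len(self.steps) != len(self.da_counts):
            raise ValueError("steps and da_counts must align")
        if self.reps_per_step < 1:
            raise ValueError("reps_per_step must be >= 1")
        if any(c < 0 or c > self.reps_per_step for c in self.da_counts):
            raise ValueError("counts must lie in [0, reps_per_step]")

    @property
    def proportions(self) -> np.ndarray:
        return np.asarray(self.da_counts, dtype=float) / self.reps_per_step


def simulate_identification(
    observer: ObserverProfile,
    draw: np.random.Generator,
    reps_per_step: int = 8,
    steps: Sequence[int] = tuple(range(1, 11)),
) -> IdentificationData:
    """Simulate binomial /dA/ counts for each continuum step (default 10
    steps x 8 repetitions = 80 trials)."""
    counts = tuple(
        int(draw.binomial(reps_per_step, p_da(observer, s))) for s in steps
    )
    return IdentificationData(tuple(int(s) for s in steps), counts, reps_per_step)


@dataclass
class Cohort:
    """A generated cohort: observer profiles plus simulated task data."""

    config: CohortConfig
    seed: int
    observers: list[ObserverProfile] = field(default_factory=list)
    identification: dict[str, IdentificationData] = field(default_factory=dict)

    def by_group(self, group: Group) -> list[ObserverProfile]:
        return [o for o in self.observers if o.group == group]


def generate_cohort(config: CohortConfig, seed: Optional[int] = None) -> Cohort:
    """Generate a full cohort (profiles + identification data).

    Staircase runs are produced separately by the staircase module so
    that staircase settings remain independent of the generating model.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    cohort = Cohort(config=config, seed=seed)
    for group, n in (("control", config.n_control), ("aphasia", config.n_aphasia)):
        prefix = "ctrl" if group == "control" else "iwa"
        for i in range(n):
            obs = make_observer(group, config, rng, f"{prefix}-{i + 1:03d}")
            cohort.observers.append(obs)
            cohort.identification[obs.participant_id] = simulate_identification(obs, rng)
    return cohort


def cohort_to_frames(cohort: Cohort):
    """Serialize a cohort to (participants, trials) DataFrames.

    ``participants`` has one row per observer with covariates, outcomes
    and the latent generating parameters flagged ``latent_*``;
    ``trials`` is the long-format identification trial table.
    """
    import pandas as pd

    part = pd.DataFrame(
        {
            "participant_id": [o.participant_id for o in cohort.observers],
            "group": [o.group for o in cohort.observers],
            "hearing_fletcher_db": [o.hearing_fletcher_db for o in cohort.observers],
            "cognition_z": [o.cognition_z for o in cohort.observers],
            "phonology_screeling": [o.phonology_screeling for o in cohort.observers],
            "fluency_count": [o.fluency_count for o in cohort.observers],
            "rtd_completed": [o.rtd_completed for o in cohort.observers],
            "id_completed": [o.id_completed for o in cohort.observers],
            "latent_rtd_x707_ms": [o.rtd_x707_ms for o in cohort.observers],
            "latent_rtd_width_log": [o.rtd_width_log for o in cohort.observers],
            "latent_id_midpoint": [o.id_midpoint for o in cohort.observers],
            "latent_id_width": [o.id_width for o in cohort.observers],
            "latent_id_guess": [o.id_guess for o in cohort.observers],
            "latent_id_lapse": [o.id_lapse for o in cohort.observers],
        }
    )
    rows = []
    for pid, data in cohort.identification.items():
        for step, count in zip(data.steps, data.da_counts):
            rows.append((pid, "phoneme_identification", step, count, data.reps_per_step))
    trials = pd.DataFrame(
        rows, columns=["participant_id", "task", "step", "da_count", "reps"]
    )
    return part, trials
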