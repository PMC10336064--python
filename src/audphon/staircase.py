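"""Rise-time discrimination task: stimulus ladder, adaptive staircase,
threshold extraction, and optional stimulus synthesis.

The task presents two 15 ms rise-time reference stimuli and one deviant
with a longer rise time (3AFC). Difficulty is controlled by a 50-level
ladder of deviant rise times, log-spaced from 699 ms (easiest) down to
16 ms (hardest). A one-up/two-down transformed staircase adjusts the
level: two consecutive correct responses move one step harder, a single
error moves one step easier, which converges on the 70.7%-correct point.
The run stops after 8 reversals (or a 87-trial cap), and the deviant
rise times at the last 4 reversals are averaged to give the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .observers import ObserverProfile, p_correct_rtd


class ConfigurationError(ValueError):
    pass


class InvalidResultError(ValueError):
    """Raised when a threshold is requested from an invalid run."""


@dataclass(frozen=True)
class Ladder:
    """Log-spaced deviant rise-time ladder (index 1 = easiest)."""

    rise_times_ms: tuple[float, ...]
    reference_rise_ms: float = 15.0
    stimulus_duration_ms: float = 800.0

    @property
    def n_levels(self) -> int:
        return len(self.rise_times_ms)

    def rise_ms(self, difficulty: int) -> float:
        """Deviant rise time at a 1-based difficulty index."""
        if not (1 <= difficulty <= self.n_levels):
            raise IndexError(f"difficulty {difficulty} outside 1..{self.n_levels}")
        return self.rise_times_ms[difficulty - 1]


def build_ladder(
    start_ms: float = 699.0, end_ms: float = 16.0, n_steps: int = 50
) -> Ladder:
    """Geometric ladder: entry k = start * (end/start)**((k-1)/(n-1))."""
    if start_ms <= 0 or end_ms <= 0 or start_ms <= end_ms:
        raise ConfigurationError(
            f"need start_ms > end_ms > 0, got {start_ms}, {end_ms}"
        )
    if n_steps < 2:
        raise ConfigurationError("n_steps must be >= 2")
    k = np.arange(n_steps)
    rts = start_ms * (end_ms / start_ms) ** (k / (n_steps - 1))
    return Ladder(tuple(float(x) for x in rts))


class StaircaseConfig(BaseModel):
    """Transformed up-down staircase settings (defaults: 1-up/2-down,
    8-reversal stop, 87-trial cap, threshold over the last 4 reversals)."""

    model_config = ConfigDict(extra="forbid")

    n_down: int = Field(default=2, ge=1)
    n_up: int = Field(default=1, ge=1)
    stop_reversals: int = Field(default=8, ge=1)
    max_trials: int = Field(default=87, ge=1)
    threshold_last_k: int = Field(default=4, ge=1)
    start_difficulty: int = Field(default=1, ge=1)
    step_size: int = Field(default=1, ge=1)

    def model_post_init(self, _ctx) -> None:
        if self.threshold_last_k > self.stop_reversals:
            raise ValueError("threshold_last_k must not exceed stop_reversals")


Move = Literal["up", "down", "none"]


@dataclass(frozen=True)
class TrialRecord:
    difficulty: int
    deviant_rise_ms: float
    correct: bool
    reversal: bool


@dataclass(frozen=True)
class StaircaseState:
    """State between trials. ``last_move`` tracks the direction of the
    last realized level change ('down' = harder, i.e. toward index 50)."""

    difficulty: int
    correct_run: int = 0
    last_move: Move = "none"
    trial_log: tuple[TrialRecord, ...] = ()
    reversal_values_ms: tuple[float, ...] = ()


@dataclass(frozen=True)
class StaircaseResult:
    trial_log: tuple[TrialRecord, ...]
    reversal_values_ms: tuple[float, ...]
    threshold_ms: Optional[float]
    valid: bool
    stop_reason: Literal["reversals", "max_trials"]


def staircase_update(
    state: StaircaseState,
    correct: bool,
    config: StaircaseConfig,
    ladder: Ladder,
) -> StaircaseState:
    """Apply one trial's outcome to the staircase.

    Two-in-a-row correct -> one step harder; an error -> one step easier;
    levels clamp to the ladder ends. A reversal is recorded when the
    realized movement direction flips relative to the previous realized
    movement; the deviant rise time logged is that of the trial where the
    flip occurs. Clamped moves that leave the level unchanged do not
    count as movement.
    """
    rise = ladder.rise_ms(state.difficulty)
    new_diff = state.difficulty
    run = state.correct_run
    intended: Move = "none"
    if correct:
        run += 1
        if run >= config.n_down:
            intended = "down"  # harder: larger index, smaller rise time
            new_diff = min(ladder.n_levels, state.difficulty + config.step_size)
            run = 0
    else:
        intended = "up"
        new_diff = max(1, state.difficulty - config.step_size)
        run = 0

    realized: Move = "none" if new_diff == state.difficulty else intended
    is_reversal = (
        realized != "none"
        and state.last_move != "none"
        and realized != state.last_move
    )
    reversals = state.reversal_values_ms + ((rise,) if is_reversal else ())
    record = TrialRecord(state.difficulty, rise, correct, is_reversal)
    return StaircaseState(
        difficulty=new_diff,
        correct_run=run,
        last_move=realized if realized != "none" else state.last_move,
        trial_log=state.trial_log + (record,),
        reversal_values_ms=reversals,
    )


ResponseFn = Callable[[float], bool]


def run_staircase(
    observer: ObserverProfile,
    config: Optional[StaircaseConfig] = None,
    ladder: Optional[Ladder] = None,
    seed: int | np.random.Generator = 0,
) -> StaircaseResult:
    """Run one full adaptive track for a simulated observer."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def respond(rise_ms: float) -> bool:
        return bool(rng.random() < p_correct_rtd(observer, rise_ms))

    return run_staircase_with_responses(respond, config, ladder)


def run_staircase_with_responses(
    respond: ResponseFn,
    config: Optional[StaircaseConfig] = None,
    ladder: Optional[Ladder] = None,
) -> StaircaseResult:
    """Run a staircase against an arbitrary response callback (used both
    by the simulator and by deterministic replay in tests)."""
    config = config or StaircaseConfig()
    ladder = ladder or build_ladder()
    state = StaircaseState(difficulty=config.start_difficulty)
    stop_reason: Literal["reversals", "max_trials"] = "max_trials"
    for _ in range(config.max_trials):
        correct = respond(ladder.rise_ms(state.difficulty))
        state = staircase_update(state, correct, config, ladder)
        if len(state.reversal_values_ms) >= config.stop_reversals:
            stop_reason = "reversals"
            break
    valid = len(state.reversal_values_ms) >= config.threshold_last_k
    threshold = (
        float(np.mean(state.reversal_values_ms[-config.threshold_last_k:]))
        if valid
        else None
    )
    return StaircaseResult(
        trial_log=state.trial_log,
        reversal_values_ms=state.reversal_values_ms,
        threshold_ms=threshold,
        valid=valid,
        stop_reason=stop_reason,
    )


def rtd_threshold(result: StaircaseResult, config: Optional[StaircaseConfig] = None) -> float:
    """Arithmetic mean of the deviant rise times at the last k reversals."""
    config = config or StaircaseConfig()
    if len(result.reversal_values_ms) < config.threshold_last_k:
        raise InvalidResultError(
            f"only {len(result.reversal_values_ms)} reversals; "
            f"{config.threshold_last_k} required — task not completed"
        )
    return float(np.mean(result.reversal_values_ms[-config.threshold_last_k:]))


def rescan_reversals(trial_log: tuple[TrialRecord, ...],
                     config: Optional[StaircaseConfig] = None,
                     ladder: Optional[Ladder] = None) -> tuple[float, ...]:
    """Recompute reversal values from a trial log alone by replaying the
    update rule (brute-force check of the online bookkeeping)."""
    config = config or StaircaseConfig()
    ladder = ladder or build_ladder()
    if not trial_log:
        return ()
    state = StaircaseState(difficulty=trial_log[0].difficulty)
    for rec in trial_log:
        assert rec.difficulty == state.difficulty, "trial log inconsistent with replay"
        state = staircase_update(state, rec.correct, config, ladder)
    return state.reversal_values_ms


def synthesize_stimulus(
    rise_ms: float,
    ladder: Optional[Ladder] = None,
    sample_rate_hz: int = 32000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Synthesize one task stimulus: a one-octave noise band centered at
    1 kHz (707-1414 Hz), 800 ms long, with a linear amplitude rise over
    ``rise_ms`` followed by a sustained plateau; peak-normalised.

    Returns the mono waveform as a float array in [-1, 1]. Presentation
    level (70 dB SPL in the original task) is calibration metadata, not
    encoded in the samples.
    """
    from scipy.signal import butter, sosfilt

    ladder = ladder or build_ladder()
    dur_ms = ladder.stimulus_duration_ms
    if rise_ms >= dur_ms:
        raise ValueError(f"rise time {rise_ms} ms must be below {dur_ms} ms duration")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(dur_ms / 1000.0 * sample_rate_hz))
    noise = rng.standard_normal(n)
    f0 = 1000.0
    low, high = f0 / math.sqrt(2.0), f0 * math.sqrt(2.0)
    sos = butter(4, [low, high], btype="bandpass", fs=sample_rate_hz, output="sos")
    band = sosfilt(sos, noise)
    n_rise = int(round(rise_ms / 1000.0 * sample_rate_hz))
    env = np.ones(n)
    if n_rise > 0:
        env[:n_rise] = np.linspace(0.0, 1.0, n_rise, endpoint=False)
    wave = band * env
    peak = np.max(np.abs(wave))
    return wave / peak if peak > 0 else wave
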