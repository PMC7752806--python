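"""Conditioning-session protocols: stimulus timing and trial schedules.

A session is delay eyeblink conditioning under a 50% partial reinforcement
schedule: a 500-ms tone CS co-terminates with a 50-ms air-puff US on half of
the trials (CS+); the other half present the tone alone (CS-).  Week 1 opens
with three US-alone exposures (UR calibration) followed by 60 acquisition
trials; Week 2 is a 30-trial retention session with no US-alone exposures.
Trial order is pseudorandom with no more than three same-kind acquisition
trials in succession.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TrialKind",
    "Week",
    "StimulusConfig",
    "TrialSpec",
    "SessionSchedule",
    "generate_schedule",
    "max_run_length",
    "sample_iti",
    "write_schedule_csv",
    "read_schedule_csv",
]


class TrialKind(str, enum.Enum):
    CS_PLUS = "CS_PLUS"
    CS_MINUS = "CS_MINUS"
    US_ALONE = "US_ALONE"


class Week(enum.IntEnum):
    WEEK1 = 1
    WEEK2 = 2


@dataclass(frozen=True)
class StimulusConfig:
    """Stimulus and sampling parameters for one conditioning session.

    Times are milliseconds unless noted; ``cs_level`` (dB) and ``us_pressure``
    (psi) are metadata only and enter no computation.
    """

    cs_duration: int = 500
    cs_frequency: float = 1200.0
    cs_level: float = 82.0
    us_duration: int = 50
    us_pressure: float = 5.0
    iti_min: float = 15.0  # seconds
    iti_max: float = 30.0  # seconds
    sample_rate: int = 1000  # Hz
    trace_duration: int = 3000
    cs_onset_in_trace: int = 1000

    def __post_init__(self) -> None:
        if not (self.cs_duration > self.us_duration > 0):
            raise ValueError("require cs_duration > us_duration > 0")
        if self.iti_min > self.iti_max:
            raise ValueError("require iti_min <= iti_max")
        if self.cs_onset_in_trace + self.cs_duration >= self.trace_duration:
            raise ValueError("CS must end before the trace does")
        if self.cs_onset_in_trace < 250:
            raise ValueError("need >= 250 ms of pre-CS baseline in the trace")

    @property
    def n_samples(self) -> int:
        return self.trace_duration * self.sample_rate // 1000

    @property
    def us_onset_in_trace(self) -> int:
        """US onset for a paired (co-terminating) trial, ms into the trace."""
        return self.cs_onset_in_trace + self.cs_duration - self.us_duration


@dataclass(frozen=True)
class TrialSpec:
    """One protocol event: trial kind plus stimulus landmarks (ms in trace)."""

    index: int
    kind: TrialKind
    iti_before: float
    cs_onset: int | None
    us_onset: int | None

    def __post_init__(self) -> None:
        if self.kind is TrialKind.CS_PLUS and (
            self.cs_onset is None or self.us_onset is None
        ):
            raise ValueError("CS+ trial needs both CS and US onsets")
        if self.kind is TrialKind.CS_MINUS and (
            self.cs_onset is None or self.us_onset is not None
        ):
            raise ValueError("CS- trial has a CS onset and no US onset")
        if self.kind is TrialKind.US_ALONE and (
            self.cs_onset is not None or self.us_onset is None
        ):
            raise ValueError("US-alone trial has a US onset and no CS onset")

    @property
    def has_cs(self) -> bool:
        return self.cs_onset is not None

    @property
    def has_us(self) -> bool:
        return self.us_onset is not None


@dataclass(frozen=True)
class SessionSchedule:
    week: Week
    trials: tuple[TrialSpec, ...]
    seed: int
    config: StimulusConfig = field(default_factory=StimulusConfig)

    @property
    def acquisition_trials(self) -> tuple[TrialSpec, ...]:
        return tuple(t for t in self.trials if t.kind is not TrialKind.US_ALONE)

    def counts(self) -> dict[TrialKind, int]:
        out = {k: 0 for k in TrialKind}
        for t in self.trials:
            out[t.kind] += 1
        return out


# trial composition per week: (n US-alone, n CS+, n CS-)
_COMPOSITION = {Week.WEEK1: (3, 30, 30), Week.WEEK2: (0, 15, 15)}
_MAX_RUN = 3


def sample_iti(config: StimulusConfig, rng: np.random.Generator) -> float:
    """Inter-trial interval in seconds, uniform over [iti_min, iti_max]."""
    return float(rng.uniform(config.iti_min, config.iti_max))


def _sample_kinds(
    n_plus: int, n_minus: int, rng: np.random.Generator, max_run: int = _MAX_RUN
) -> list[TrialKind]:
    """Uniformly sample an admissible CS+/CS- order by rejection.

    Shuffles the multiset of trial kinds and rejects any permutation with a
    same-kind run longer than ``max_run``; every admissible order is therefore
    equally likely.
    """
    kinds = np.array([0] * n_plus + [1] * n_minus, dtype=np.int8)
    while True:
        rng.shuffle(kinds)
        if _longest_run(kinds) <= max_run:
            return [TrialKind.CS_PLUS if k == 0 else TrialKind.CS_MINUS for k in kinds]


def _longest_run(codes: np.ndarray) -> int:
    if codes.size == 0:
        return 0
    change = np.flatnonzero(np.diff(codes) != 0)
    bounds = np.concatenate(([-1], change, [codes.size - 1]))
    return int(np.max(np.diff(bounds)))


def generate_schedule(
    week: Week | int,
    config: StimulusConfig | None = None,
    seed: int = 0,
) -> SessionSchedule:
    """Generate one session schedule; identical for identical seeds."""
    week = Week(week)
    config = config or StimulusConfig()
    rng = np.random.default_rng(seed)
    n_us_alone, n_plus, n_minus = _COMPOSITION[week]

    kinds = [TrialKind.US_ALONE] * n_us_alone
    kinds += _sample_kinds(n_plus, n_minus, rng)

    trials = []
    for i, kind in enumerate(kinds):
        cs_onset = config.cs_onset_in_trace if kind is not TrialKind.US_ALONE else None
        us_onset = (
            config.us_onset_in_trace if kind is not TrialKind.CS_MINUS else None
        )
        trials.append(
            TrialSpec(
                index=i,
                kind=kind,
                iti_before=sample_iti(config, rng),
                cs_onset=cs_onset,
                us_onset=us_onset,
            )
        )
    return SessionSchedule(week=week, trials=tuple(trials), seed=seed, config=config)


def max_run_length(schedule: SessionSchedule) -> int:
    """Longest run of consecutive same-kind acquisition trials."""
    acq = schedule.acquisition_trials
    if not schedule.trials:
        raise ValueError("empty schedule")
    codes = np.array(
        [0 if t.kind is TrialKind.CS_PLUS else 1 for t in acq], dtype=np.int8
    )
    return _longest_run(codes)


def write_schedule_csv(schedule: SessionSchedule, path) -> None:
    rows = [
        {
            "trial_index": t.index,
            "kind": t.kind.value,
            "iti_s": t.iti_before,
            "cs_onset_ms": t.cs_onset,
            "us_onset_ms": t.us_onset,
        }
        for t in schedule.trials
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_schedule_csv(path, week: Week | int = Week.WEEK1,
                      config: StimulusConfig | None = None,
                      seed: int = -1) -> SessionSchedule:
    df = pd.read_csv(path, float_precision="round_trip")
    trials = []
    for _, r in df.iterrows():
        trials.append(
            TrialSpec(
                index=int(r.trial_index),
                kind=TrialKind(r.kind),
                iti_before=float(r.iti_s),
                cs_onset=None if pd.isna(r.cs_onset_ms) else int(r.cs_onset_ms),
                us_onset=None if pd.isna(r.us_onset_ms) else int(r.us_onset_ms),
            )
        )
    return SessionSchedule(
        week=Week(week), trials=tuple(trials), seed=seed,
        config=config or StimulusConfig(),
    )
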