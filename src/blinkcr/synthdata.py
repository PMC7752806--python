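"""Synthetic cohorts: latent learning profiles, questionnaires, and EMG.

The generator emulates the study design end to end so every downstream
stage is testable without recorded data: subjects carry a latent learning
profile (HIGH / MID / LOW, saturating-growth CR probability per training
block), group labels (PTSD+/-, mTBI+/-) with questionnaire totals drawn to
match the published group means and SDs, and per-trial EMG traces built
from band-limited (1-30 Hz) Gaussian baseline noise plus smooth blink
bursts (CR inside the scoring window, UR after the US, occasional
spontaneous blinks elsewhere).

Profile parameters are stand-ins chosen to qualitatively match the shape of
the published learning curves (fast/high, gradual/intermediate, flat/low);
the source article reports those curves only graphically.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .protocol import (
    SessionSchedule,
    StimulusConfig,
    TrialKind,
    TrialSpec,
    Week,
    generate_schedule,
)

__all__ = [
    "ProfileName",
    "LearningProfile",
    "DEFAULT_PROFILES",
    "TbiScreen",
    "SubjectRecord",
    "EMGTrace",
    "NoiseParams",
    "cr_probability",
    "simulate_trial_emg",
    "sample_cohort",
    "simulate_study",
    "StudyData",
    "cohort_to_frame",
    "frame_to_cohort",
]


class ProfileName(str, enum.Enum):
    HIGH = "HIGH"
    MID = "MID"
    LOW = "LOW"


@dataclass(frozen=True)
class LearningProfile:
    """Saturating-growth CR-probability curve for one latent learner type.

    Week-1 block ``b`` has CR probability
    ``p_start + (p_asymptote - p_start) * (1 - exp(-rate * b))``; Week 2
    restarts from ``retention`` times the Week-1 final value and grows
    toward the asymptote at the same rate.
    """

    name: ProfileName
    p_start: float
    p_asymptote: float
    rate: float
    retention: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_start <= self.p_asymptote <= 1.0):
            raise ValueError("require 0 <= p_start <= p_asymptote <= 1")
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if not (0.0 <= self.retention <= 1.2):
            raise ValueError("retention must lie in [0, 1.2]")


DEFAULT_PROFILES: dict[ProfileName, LearningProfile] = {
    ProfileName.HIGH: LearningProfile(ProfileName.HIGH, 0.40, 0.70, 0.9, 1.0),
    ProfileName.MID: LearningProfile(ProfileName.MID, 0.05, 0.50, 0.35, 0.9),
    ProfileName.LOW: LearningProfile(ProfileName.LOW, 0.05, 0.14, 0.5, 0.85),
}

_WEEK_BLOCKS = {Week.WEEK1: 6, Week.WEEK2: 3}


def cr_probability(
    profile: LearningProfile, week: Week | int, block: int
) -> float:
    """CR probability for one training block (1-based within the week)."""
    week = Week(week)
    n_blocks = _WEEK_BLOCKS[week]
    if not 1 <= block <= n_blocks:
        raise ValueError(f"block must be in 1..{n_blocks} for {week.name}")
    ps, pa, r = profile.p_start, profile.p_asymptote, profile.rate
    if r == np.inf:
        w1 = lambda b: pa  # noqa: E731 - limit case
    else:
        w1 = lambda b: ps + (pa - ps) * (1.0 - np.exp(-r * b))  # noqa: E731
    if week is Week.WEEK1:
        return float(np.clip(w1(block), 0.0, 1.0))
    start = profile.retention * w1(_WEEK_BLOCKS[Week.WEEK1])
    target = max(pa, start)
    if r == np.inf:
        p = target
    else:
        p = start + (target - start) * (1.0 - np.exp(-r * (block - 1)))
    return float(np.clip(p, 0.0, 1.0))


# ---------------------------------------------------------------------------
# EMG synthesis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseParams:
    """Amplitudes are unitless envelope units; times ms; ``mode`` selects
    whether traces are the post-preprocessing envelope directly
    ("envelope", flagged pre-filtered) or an oscillatory raw signal
    (envelope x 15 Hz carrier) that the detector must band-pass itself."""

    sigma_baseline: float = 0.05
    blink_amp_median: float = 0.65  # >= 3x the 0.2 detection threshold
    blink_amp_sigma: float = 0.25  # log-scale SD of the log-normal
    ur_amp_median: float = 1.0
    width_fwhm_range: tuple[float, float] = (30.0, 60.0)
    cr_latency_range: tuple[float, float] = (120.0, 400.0)  # ms after CS
    ur_latency_range: tuple[float, float] = (25.0, 60.0)  # ms after US
    spontaneous_rate: float = 0.05  # blinks per trial, Poisson
    spontaneous_in_window: bool = False
    mode: str = "envelope"  # or "raw"
    carrier_hz: float = 15.0


@dataclass(frozen=True)
class EMGTrace:
    samples: np.ndarray
    trial: TrialSpec
    subject_id: str = ""
    prefiltered: bool = True


def _bandlimited_noise(
    n_trials: int, n_samples: int, sigma: float, band: tuple[float, float],
    sample_rate: int, rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian noise with power confined to ``band`` (spectral synthesis)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.zeros((n_trials, freqs.size), dtype=complex)
    nk = int(keep.sum())
    spec[:, keep] = rng.normal(size=(n_trials, nk)) + 1j * rng.normal(
        size=(n_trials, nk)
    )
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return sigma * x / sd


def _gauss_bump(
    n_samples: int, peak_ms: float, amp: float, fwhm_ms: float, sample_rate: int
) -> np.ndarray:
    sigma = fwhm_ms / 2.3548200450309493  # FWHM -> Gaussian width
    out = np.zeros(n_samples)
    ms_per_sample = 1000.0 / sample_rate
    lo = max(0, int((peak_ms - 4 * sigma) / ms_per_sample))
    hi = min(n_samples, int((peak_ms + 4 * sigma) / ms_per_sample) + 1)
    t = np.arange(lo, hi) * ms_per_sample
    out[lo:hi] = amp * np.exp(-0.5 * ((t - peak_ms) / sigma) ** 2)
    return out


def _draw_bump(rng: np.random.Generator, noise: NoiseParams, median: float):
    amp = float(median * np.exp(rng.normal(0.0, noise.blink_amp_sigma)))
    fwhm = float(rng.uniform(*noise.width_fwhm_range))
    return amp, fwhm


def _trial_envelope(
    trial: TrialSpec,
    cr_draw: bool,
    config: StimulusConfig,
    noise: NoiseParams,
    rng: np.random.Generator,
) -> np.ndarray:
    n = config.n_samples
    env = np.zeros(n)
    if trial.has_us:
        amp, fwhm = _draw_bump(rng, noise, noise.ur_amp_median)
        lat = rng.uniform(*noise.ur_latency_range)
        env += _gauss_bump(n, trial.us_onset + lat, amp, fwhm, config.sample_rate)
    if cr_draw and trial.has_cs:
        amp, fwhm = _draw_bump(rng, noise, noise.blink_amp_median)
        lat = rng.uniform(*noise.cr_latency_range)
        env += _gauss_bump(n, trial.cs_onset + lat, amp, fwhm, config.sample_rate)
    n_spont = rng.poisson(noise.spontaneous_rate)
    for _ in range(n_spont):
        amp, fwhm = _draw_bump(rng, noise, noise.blink_amp_median)
        peak = _spontaneous_position(trial, config, noise, rng)
        env += _gauss_bump(n, peak, amp, fwhm, config.sample_rate)
    return env


def _spontaneous_position(trial, config, noise, rng) -> float:
    """Place a spontaneous blink, by default clear of the CR scoring window."""
    lo, hi = 100.0, config.trace_duration - 100.0
    if noise.spontaneous_in_window or not trial.has_cs:
        return float(rng.uniform(lo, hi))
    w0 = trial.cs_onset  # keep a guard band before the window start
    w1 = (trial.us_onset or trial.cs_onset + 450) + 100.0
    for _ in range(100):
        pos = float(rng.uniform(lo, hi))
        if not (w0 <= pos <= w1):
            return pos
    return lo


def simulate_trial_emg(
    trial: TrialSpec,
    cr_draw: bool,
    config: StimulusConfig | None = None,
    noise: NoiseParams | None = None,
    rng: np.random.Generator | None = None,
    subject_id: str = "",
) -> EMGTrace:
    """Simulate one trial's EMG trace (see :class:`NoiseParams` for modes)."""
    config = config or StimulusConfig()
    noise = noise or NoiseParams()
    rng = rng if rng is not None else np.random.default_rng()
    env = _trial_envelope(trial, cr_draw, config, noise, rng)
    base = _bandlimited_noise(
        1, config.n_samples, noise.sigma_baseline, (1.0, 30.0),
        config.sample_rate, rng,
    )[0]
    if noise.mode == "envelope":
        return EMGTrace(env + base, trial, subject_id, prefiltered=True)
    t = np.arange(config.n_samples) / config.sample_rate
    phase = rng.uniform(0, 2 * np.pi)
    carrier = np.sin(2 * np.pi * noise.carrier_hz * t + phase)
    # pi/2 restores the rectified-mean so the post-preprocessing envelope
    # carries the same burst amplitude as envelope mode
    return EMGTrace(
        (np.pi / 2) * env * carrier + base, trial, subject_id, prefiltered=False
    )


def simulate_session_emg(
    schedule: SessionSchedule,
    cr_draws: np.ndarray,
    noise: NoiseParams | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """All traces of a session as a (trials x samples) matrix."""
    noise = noise or NoiseParams()
    rng = rng if rng is not None else np.random.default_rng()
    config = schedule.config
    n = config.n_samples
    env = np.empty((len(schedule.trials), n))
    for i, trial in enumerate(schedule.trials):
        env[i] = _trial_envelope(trial, bool(cr_draws[i]), config, noise, rng)
    base = _bandlimited_noise(
        len(schedule.trials), n, noise.sigma_baseline, (1.0, 30.0),
        config.sample_rate, rng,
    )
    if noise.mode == "envelope":
        return env + base
    t = np.arange(n) / config.sample_rate
    phases = rng.uniform(0, 2 * np.pi, size=(env.shape[0], 1))
    carrier = np.sin(2 * np.pi * noise.carrier_hz * t[None, :] + phases)
    return (np.pi / 2) * env * carrier + base


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TbiScreen:
    """Minimal head-injury screen: an injury event, whether consciousness was
    altered, and loss-of-consciousness duration (minutes; None = no LOC)."""

    event: bool
    alteration_of_consciousness: bool
    loc_duration_min: float | None = None


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    age: float
    sex: str
    latent_profile: ProfileName
    ptsd_group: bool
    mtbi_group: bool
    pcl5_items: tuple[int, ...]
    phq8_items: tuple[int, ...]
    ambi_items: tuple[int, ...]
    tbi_screen: TbiScreen

    def __post_init__(self) -> None:
        if len(self.pcl5_items) != 20 or not all(0 <= v <= 4 for v in self.pcl5_items):
            raise ValueError("PCL-5 needs 20 items in 0..4")
        if len(self.phq8_items) != 8 or not all(0 <= v <= 3 for v in self.phq8_items):
            raise ValueError("PHQ-8 needs 8 items in 0..3")
        if len(self.ambi_items) != 16 or not all(0 <= v <= 2 for v in self.ambi_items):
            raise ValueError("AMBI needs 16 items in 0..2")
        if not 18 <= self.age <= 65:
            raise ValueError("age must lie in [18, 65]")


# Published per-group descriptives: (mean, sd) keyed by (ptsd, mtbi).
GROUP_STATS: dict[tuple[bool, bool], dict[str, tuple[float, float]]] = {
    (False, False): {"age": (46, 11.50), "pcl": (10.00, 6.63), "phq": (7.50, 4.31), "ambi": (16.63, 6.68)},
    (False, True): {"age": (51, 10.00), "pcl": (19.19, 8.52), "phq": (5.57, 3.81), "ambi": (16.91, 5.70)},
    (True, False): {"age": (50, 10.50), "pcl": (47.67, 11.24), "phq": (14.92, 7.13), "ambi": (20.25, 6.37)},
    (True, True): {"age": (45, 12.00), "pcl": (51.46, 9.70), "phq": (12.46, 4.37), "ambi": (22.08, 6.86)},
}

# Group sizes 8/21/12/13 of n=54, as proportions.
DEFAULT_COMPOSITION: dict[tuple[bool, bool], float] = {
    (False, False): 8 / 54,
    (False, True): 21 / 54,
    (True, False): 12 / 54,
    (True, True): 13 / 54,
}

# P(profile | PTSD status); PTSD+ enriched among proficient learners, from
# the published profile-by-PTSD cross-tabulation (10/14 HIGH, 7/13 MID,
# 8/27 LOW learners PTSD+ at n=25 PTSD+ / 29 PTSD-).
DEFAULT_PROFILE_MIX: dict[bool, dict[ProfileName, float]] = {
    True: {ProfileName.HIGH: 10 / 25, ProfileName.MID: 7 / 25, ProfileName.LOW: 8 / 25},
    False: {ProfileName.HIGH: 4 / 29, ProfileName.MID: 6 / 29, ProfileName.LOW: 19 / 29},
}

_SEX_P_MALE = 43 / 54  # 43 of 54 published participants male


def _truncnorm_int(
    mean: float, sd: float, lo: int, hi: int, rng: np.random.Generator
) -> int:
    if not lo <= hi:
        raise ValueError("empty truncation range")
    if sd <= 0:
        val = mean
    else:
        a, b = (lo - 0.5 - mean) / sd, (hi + 0.5 - mean) / sd
        val = spstats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)
    out = int(np.clip(round(val), lo, hi))
    return out


def _decompose_total(
    total: int, n_items: int, item_max: int, rng: np.random.Generator
) -> tuple[int, ...]:
    """Distribute an integer total over items by random unit increments."""
    if not 0 <= total <= n_items * item_max:
        raise ValueError("total outside instrument range")
    items = np.zeros(n_items, dtype=int)
    for _ in range(total):
        open_items = np.flatnonzero(items < item_max)
        items[open_items[rng.integers(open_items.size)]] += 1
    return tuple(int(v) for v in items)


def _largest_remainder_counts(n: int, props: np.ndarray) -> np.ndarray:
    raw = props * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    return counts


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    # fixed per-subject child stream: cohorts extend without reshuffling
    return np.random.default_rng(np.random.SeedSequence([seed, 1000 + index]))


def sample_cohort(
    n: int = 54,
    composition: dict[tuple[bool, bool], float] | None = None,
    profile_mix_by_group: dict[bool, dict[ProfileName, float]] | None = None,
    seed: int = 0,
    group_stats: dict | None = None,
) -> list[SubjectRecord]:
    """Draw a cohort with group structure matching the published tables.

    Questionnaire totals per group are truncated-normal draws around the
    published group means/SDs (PCL-5 additionally truncated on the
    group-defining side of the 33 cut-off so the drawn label is consistent
    with rescoring), then decomposed into item responses.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    composition = composition or DEFAULT_COMPOSITION
    profile_mix = profile_mix_by_group or DEFAULT_PROFILE_MIX
    group_stats = group_stats or GROUP_STATS
    keys = list(composition)
    props = np.array([composition[k] for k in keys], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("composition proportions must sum to 1")
    counts = _largest_remainder_counts(n, props)
    groups: list[tuple[bool, bool]] = []
    for k, c in zip(keys, counts):
        groups += [k] * int(c)

    cohort = []
    for i, (ptsd, mtbi) in enumerate(groups):
        rng = _subject_rng(seed, i)
        stats = group_stats[(ptsd, mtbi)]
        age = _truncnorm_int(*stats["age"], 18, 65, rng)
        pcl_lo, pcl_hi = (33, 80) if ptsd else (0, 32)
        pcl_total = _truncnorm_int(*stats["pcl"], pcl_lo, pcl_hi, rng)
        phq_total = _truncnorm_int(*stats["phq"], 0, 24, rng)
        ambi_total = _truncnorm_int(*stats["ambi"], 0, 32, rng)
        mix = profile_mix[ptsd]
        names = list(mix)
        profile = names[
            rng.choice(len(names), p=np.array([mix[m] for m in names]))
        ]
        if mtbi:
            loc = None if rng.uniform() < 0.5 else float(rng.uniform(1, 25))
            screen = TbiScreen(True, True, loc)
        else:
            screen = (
                TbiScreen(False, False, None)
                if rng.uniform() < 0.7
                else TbiScreen(True, False, None)
            )
        cohort.append(
            SubjectRecord(
                subject_id=f"S{i:03d}",
                age=float(age),
                sex="M" if rng.uniform() < _SEX_P_MALE else "F",
                latent_profile=ProfileName(profile),
                ptsd_group=ptsd,
                mtbi_group=mtbi,
                pcl5_items=_decompose_total(pcl_total, 20, 4, rng),
                phq8_items=_decompose_total(phq_total, 8, 3, rng),
                ambi_items=_decompose_total(ambi_total, 16, 2, rng),
                tbi_screen=screen,
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# Full-study simulation
# ---------------------------------------------------------------------------


@dataclass
class StudyData:
    """One simulated study: cohort, schedules, traces and the ground truth."""

    cohort: list[SubjectRecord]
    schedules: dict[tuple[str, Week], SessionSchedule]
    traces: dict[tuple[str, Week], np.ndarray]  # trials x samples, envelope units
    truth: pd.DataFrame  # subject_id, week, trial_index, kind, block, p_cr, cr_draw
    config: StimulusConfig
    noise: NoiseParams
    seed: int


def _session_seed(seed: int, subject_index: int, week: int) -> int:
    ss = np.random.SeedSequence([seed, subject_index, week])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_study(
    cohort: list[SubjectRecord],
    config: StimulusConfig | None = None,
    noise: NoiseParams | None = None,
    seed: int = 0,
    profiles: dict[ProfileName, LearningProfile] | None = None,
    with_traces: bool = True,
    block_size: int = 10,
    weeks: tuple[Week, ...] = (Week.WEEK1, Week.WEEK2),
) -> StudyData:
    """Simulate both sessions for every subject.

    Per acquisition trial the CR indicator is Bernoulli with the subject's
    profile- and block-specific probability; the truth table retains every
    draw for parameter-recovery tests.  ``with_traces=False`` skips EMG
    synthesis (truth-level simulations for statistical calibration).
    """
    config = config or StimulusConfig()
    noise = noise or NoiseParams()
    profiles = profiles or DEFAULT_PROFILES
    schedules: dict[tuple[str, Week], SessionSchedule] = {}
    traces: dict[tuple[str, Week], np.ndarray] = {}
    rows = []
    for i, subj in enumerate(cohort):
        profile = profiles[subj.latent_profile]
        for week in weeks:
            sched = generate_schedule(week, config, _session_seed(seed, i, week))
            schedules[(subj.subject_id, week)] = sched
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, i, int(week), 7])
            )
            cr_draws = np.zeros(len(sched.trials), dtype=bool)
            acq_pos = 0
            for j, trial in enumerate(sched.trials):
                if trial.kind is TrialKind.US_ALONE:
                    p = 0.0
                    block = 0
                else:
                    block = acq_pos // block_size + 1
                    p = cr_probability(profile, week, block)
                    cr_draws[j] = rng.uniform() < p
                    acq_pos += 1
                rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "week": int(week),
                        "trial_index": trial.index,
                        "kind": trial.kind.value,
                        "block": block,
                        "p_cr": p,
                        "cr_draw": bool(cr_draws[j]),
                    }
                )
            if with_traces:
                traces[(subj.subject_id, week)] = simulate_session_emg(
                    sched, cr_draws, noise, rng
                )
    return StudyData(
        cohort=cohort,
        schedules=schedules,
        traces=traces,
        truth=pd.DataFrame(rows),
        config=config,
        noise=noise,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Cohort (de)serialization
# ---------------------------------------------------------------------------


def cohort_to_frame(cohort: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for s in cohort:
        row = {
            "subject_id": s.subject_id,
            "age": s.age,
            "sex": s.sex,
            "latent_profile": s.latent_profile.value,
            "ptsd_group": s.ptsd_group,
            "mtbi_group": s.mtbi_group,
            "tbi_event": s.tbi_screen.event,
            "tbi_aoc": s.tbi_screen.alteration_of_consciousness,
            "tbi_loc_min": s.tbi_screen.loc_duration_min,
        }
        row.update({f"pcl{i + 1:02d}": v for i, v in enumerate(s.pcl5_items)})
        row.update({f"phq{i + 1:02d}": v for i, v in enumerate(s.phq8_items)})
        row.update({f"ambi{i + 1:02d}": v for i, v in enumerate(s.ambi_items)})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cohort(df: pd.DataFrame) -> list[SubjectRecord]:
    cohort = []
    for _, r in df.iterrows():
        cohort.append(
            SubjectRecord(
                subject_id=str(r.subject_id),
                age=float(r.age),
                sex=str(r.sex),
                latent_profile=ProfileName(r.latent_profile),
                ptsd_group=bool(r.ptsd_group),
                mtbi_group=bool(r.mtbi_group),
                pcl5_items=tuple(int(r[f"pcl{i + 1:02d}"]) for i in range(20)),
                phq8_items=tuple(int(r[f"phq{i + 1:02d}"]) for i in range(8)),
                ambi_items=tuple(int(r[f"ambi{i + 1:02d}"]) for i in range(16)),
                tbi_screen=TbiScreen(
                    bool(r.tbi_event),
                    bool(r.tbi_aoc),
                    None if pd.isna(r.tbi_loc_min) else float(r.tbi_loc_min),
                ),
            )
        )
    return cohort
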