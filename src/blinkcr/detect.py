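"""Per-trial EMG processing and CR/UR detection.

The detector reproduces a conventional human eyeblink-conditioning scoring
chain: zero-phase 1-30 Hz band-pass (the recording amplifier's passband),
full-wave rectification and a short moving-average smooth, then peak
detection inside the response window with three rejection criteria:

* absolute amplitude: the peak must exceed a fixed unitless threshold (0.2);
* baseline criterion: the peak must exceed the 250-ms pre-stimulus baseline
  mean plus ``baseline_k`` (default 2) standard deviations;
* slope criterion: the rising and falling slopes measured 25 ms on either
  side of the peak (the COS 1 / COS 2 coefficients) must both be steep
  enough to resemble a genuine blink.

A conditioned response (CR) is a passing peak inside [CS onset + 80 ms,
US onset); an unconditional response (UR) is a passing peak in a window
after US onset.  The CR window on CS- trials ends at the virtual US onset
(CS onset + 450 ms at default timing) so CS+ and CS- trials are scored over
identical windows.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .protocol import StimulusConfig, TrialKind, TrialSpec

__all__ = [
    "DetectionConfig",
    "RejectionReason",
    "BlinkEvent",
    "TrialResult",
    "preprocess",
    "baseline_stats",
    "classify_cr",
    "classify_ur",
    "classify_session",
]


class RejectionReason(str, enum.Enum):
    BELOW_THRESHOLD = "BELOW_THRESHOLD"
    BELOW_BASELINE_CRITERION = "BELOW_BASELINE_CRITERION"
    SLOPE_TOO_SHALLOW = "SLOPE_TOO_SHALLOW"


@dataclass(frozen=True)
class DetectionConfig:
    """Detection parameters (times in ms, amplitudes unitless).

    ``min_slope`` is the one free parameter the scoring convention leaves
    open: the slope criterion is only qualitative ("steep enough to be a
    blink").  The default 0.004 /ms corresponds to a 0.2-amplitude rise over
    50 ms and separates simulated blink bursts from slow drifts; it should
    be treated as a tunable.
    """

    amplitude_threshold: float = 0.2
    baseline_window: int = 250
    baseline_k: float = 2.0
    cr_window_start: int = 80
    cr_window_end: int = 450  # CS- virtual US onset, ms after CS onset
    slope_halfwidth: int = 25
    min_slope: float = 0.004
    smoothing_halfwidth: int = 12
    band: tuple[float, float] = (1.0, 30.0)
    ur_window: tuple[int, int] = (20, 500)  # ms after US onset

    def __post_init__(self) -> None:
        if min(
            self.amplitude_threshold,
            self.baseline_window,
            self.baseline_k,
            self.cr_window_start,
            self.slope_halfwidth,
            self.min_slope,
            self.smoothing_halfwidth,
        ) <= 0:
            raise ValueError("all detection parameters must be positive")
        if self.cr_window_start >= self.cr_window_end:
            raise ValueError("CR window start must precede its end")


@dataclass(frozen=True)
class BlinkEvent:
    peak_time: int  # ms in trace
    peak_amplitude: float
    slope_fwd: float  # COS 1, rising slope into the peak
    slope_bwd: float  # COS 2, falling slope out of the peak
    passed: bool
    rejection_reasons: frozenset[RejectionReason] = frozenset()

    def __post_init__(self) -> None:
        if self.passed != (len(self.rejection_reasons) == 0):
            raise ValueError("passed must mirror empty rejection_reasons")


@dataclass(frozen=True)
class TrialResult:
    trial: TrialSpec
    cr_present: bool
    cr_event: BlinkEvent | None
    ur_present: bool | None
    ur_magnitude: float | None
    baseline_mean: float
    baseline_sd: float


def _bandpass_sos(config: DetectionConfig, sample_rate: int):
    lo, hi = config.band
    return sps.butter(6, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")


def preprocess(
    trace,
    config: DetectionConfig | None = None,
    sample_rate: int = 1000,
    prefiltered: bool | None = None,
) -> np.ndarray:
    """Band-pass (unless pre-filtered), rectify, smooth.  Length-preserving.

    Accepts a raw sample vector, a 2-D (trials x samples) array, or an
    :class:`~blinkcr.synthdata.EMGTrace`-like object carrying ``samples`` and
    a ``prefiltered`` flag set by the acquisition chain.
    """
    config = config or DetectionConfig()
    if hasattr(trace, "samples"):
        if prefiltered is None:
            prefiltered = bool(getattr(trace, "prefiltered", False))
        x = np.asarray(trace.samples, dtype=float)
    else:
        x = np.asarray(trace, dtype=float)
        prefiltered = bool(prefiltered)
    if x.shape[-1] < 500:
        raise ValueError("trace too short to filter reliably (< 500 samples)")
    if not prefiltered:
        # generous padding suppresses the slow start-up transient of the
        # 1-Hz high-pass edge
        padlen = min(x.shape[-1] - 1, 500)
        x = sps.sosfiltfilt(
            _bandpass_sos(config, sample_rate), x, axis=-1, padlen=padlen
        )
    env = np.abs(x)
    width = 2 * config.smoothing_halfwidth * sample_rate // 1000 + 1
    kernel = np.ones(width) / width
    if env.ndim == 1:
        env = np.convolve(env, kernel, mode="same")
    else:
        from scipy.ndimage import uniform_filter1d

        env = uniform_filter1d(env, size=width, axis=-1, mode="constant")
    return env


def baseline_stats(
    envelope: np.ndarray, trial: TrialSpec, config: DetectionConfig | None = None
) -> tuple[float, float]:
    """Mean and SD over the baseline window immediately before stimulus onset.

    CS trials use the window before CS onset; US-alone trials the window
    before US onset.  SD is the sample standard deviation (ddof=1).
    """
    config = config or DetectionConfig()
    onset = trial.cs_onset if trial.has_cs else trial.us_onset
    if onset is None or onset < config.baseline_window:
        raise ValueError("insufficient pre-stimulus samples for the baseline")
    seg = np.asarray(envelope[onset - config.baseline_window : onset], dtype=float)
    return float(seg.mean()), float(seg.std(ddof=1))


def _evaluate_peak(
    envelope: np.ndarray,
    peak: int,
    baseline_mean: float,
    baseline_sd: float,
    config: DetectionConfig,
) -> BlinkEvent:
    h = config.slope_halfwidth
    amp = float(envelope[peak])
    left = float(envelope[peak - h]) if peak - h >= 0 else float(envelope[0])
    right = (
        float(envelope[peak + h])
        if peak + h < envelope.size
        else float(envelope[-1])
    )
    slope_fwd = (amp - left) / h
    slope_bwd = (right - amp) / h
    reasons = set()
    if amp <= config.amplitude_threshold:
        reasons.add(RejectionReason.BELOW_THRESHOLD)
    if amp <= baseline_mean + config.baseline_k * baseline_sd:
        reasons.add(RejectionReason.BELOW_BASELINE_CRITERION)
    if min(slope_fwd, abs(slope_bwd)) < config.min_slope:
        reasons.add(RejectionReason.SLOPE_TOO_SHALLOW)
    return BlinkEvent(
        peak_time=int(peak),
        peak_amplitude=amp,
        slope_fwd=slope_fwd,
        slope_bwd=slope_bwd,
        passed=not reasons,
        rejection_reasons=frozenset(reasons),
    )


def _scan_window(
    envelope: np.ndarray,
    start: int,
    end: int,
    baseline_mean: float,
    baseline_sd: float,
    config: DetectionConfig,
) -> tuple[BlinkEvent | None, BlinkEvent | None]:
    """Return (earliest passing event, best-rejected event) in [start, end)."""
    if end <= start:
        raise ValueError("empty scoring window; check stimulus timing")
    # scan one sample beyond each edge so maxima at the window boundaries
    # are seen, then keep only peaks inside the half-open window
    lo = max(start - 1, 0)
    hi = min(end + 1, envelope.shape[-1])
    seg = envelope[lo:hi]
    peaks, _ = sps.find_peaks(seg)
    peaks = [lo + int(p) for p in peaks if start <= lo + p < end]
    best_rejected = None
    for p in peaks:  # time order; earliest passing candidate wins
        ev = _evaluate_peak(envelope, p, baseline_mean, baseline_sd, config)
        if ev.passed:
            return ev, best_rejected
        if best_rejected is None or ev.peak_amplitude > best_rejected.peak_amplitude:
            best_rejected = ev
    return None, best_rejected


def _cr_window(trial: TrialSpec, config: DetectionConfig) -> tuple[int, int]:
    start = trial.cs_onset + config.cr_window_start
    end = trial.us_onset if trial.has_us else trial.cs_onset + config.cr_window_end
    return start, end


def classify_cr(
    envelope: np.ndarray, trial: TrialSpec, config: DetectionConfig | None = None
) -> TrialResult:
    """Score one CS trial for a conditioned response.

    Candidate peaks are local maxima of the smoothed envelope inside the
    half-open window [CS onset + 80 ms, US onset); a CR is declared iff some
    candidate passes all three criteria, and the earliest passing candidate
    is reported.
    """
    config = config or DetectionConfig()
    if not trial.has_cs:
        raise ValueError("classify_cr requires a CS trial")
    bmean, bsd = baseline_stats(envelope, trial, config)
    start, end = _cr_window(trial, config)
    event, rejected = _scan_window(envelope, start, end, bmean, bsd, config)
    ur_present: bool | None = None
    ur_magnitude: float | None = None
    if trial.has_us:
        ur_present, ur_magnitude = _ur_from_envelope(envelope, trial, bmean, bsd, config)
    return TrialResult(
        trial=trial,
        cr_present=event is not None,
        cr_event=event if event is not None else rejected,
        ur_present=ur_present,
        ur_magnitude=ur_magnitude,
        baseline_mean=bmean,
        baseline_sd=bsd,
    )


def _ur_from_envelope(envelope, trial, bmean, bsd, config):
    lo, hi = config.ur_window
    start = trial.us_onset + lo
    end = min(trial.us_onset + hi + 1, envelope.shape[-1] - 1)
    event, _ = _scan_window(envelope, start, end, bmean, bsd, config)
    if event is None:
        return False, 0.0
    return True, float(event.peak_amplitude - bmean)


def classify_ur(
    envelope: np.ndarray, trial: TrialSpec, config: DetectionConfig | None = None
) -> tuple[bool, float]:
    """Score a US trial for the unconditional (reflex) response.

    Applies the same three criteria in the window after US onset and returns
    ``(present, magnitude)`` with magnitude = peak amplitude - baseline mean
    (0 when absent).
    """
    config = config or DetectionConfig()
    if not trial.has_us:
        raise ValueError("classify_ur requires a trial with a US")
    bmean, bsd = baseline_stats(envelope, trial, config)
    return _ur_from_envelope(envelope, trial, bmean, bsd, config)


def classify_session(
    traces: np.ndarray,
    trials: list[TrialSpec],
    config: DetectionConfig | None = None,
    sample_rate: int = 1000,
    prefiltered: bool = True,
) -> list[TrialResult]:
    """Score a whole session at once (trials x samples matrix).

    Equivalent to preprocessing and classifying each trial individually; the
    batch path exists because the closed-loop calibration suites score tens
    of thousands of trials.
    """
    config = config or DetectionConfig()
    env = preprocess(traces, config, sample_rate=sample_rate, prefiltered=prefiltered)
    out = []
    for row, trial in zip(env, trials):
        if trial.has_cs:
            out.append(classify_cr(row, trial, config))
        else:
            bmean, bsd = baseline_stats(row, trial, config)
            ur_present, ur_mag = _ur_from_envelope(row, trial, bmean, bsd, config)
            out.append(
                TrialResult(
                    trial=trial,
                    cr_present=False,
                    cr_event=None,
                    ur_present=ur_present,
                    ur_magnitude=ur_mag,
                    baseline_mean=bmean,
                    baseline_sd=bsd,
                )
            )
    return out


def results_to_frame(results: list[TrialResult], subject_id: str = "", week: int = 0):
    """Tidy per-trial results table (one row per trial)."""
    import pandas as pd

    rows = []
    for r in results:
        ev = r.cr_event
        rows.append(
            {
                "subject_id": subject_id,
                "week": week,
                "trial_index": r.trial.index,
                "kind": r.trial.kind.value,
                "cr_present": r.cr_present,
                "cr_latency_ms": (
                    ev.peak_time - r.trial.cs_onset
                    if (r.cr_present and ev is not None)
                    else np.nan
                ),
                "cr_amplitude": ev.peak_amplitude if (r.cr_present and ev) else np.nan,
                "ur_present": r.ur_present,
                "ur_magnitude": r.ur_magnitude,
                "rejection_reasons": (
                    ";".join(sorted(x.value for x in ev.rejection_reasons))
                    if (ev is not None and not r.cr_present)
                    else ""
                ),
            }
        )
    return pd.DataFrame(rows)
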