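import numpy as np
import pytest

from blinkcr.detect import DetectionConfig
from blinkcr.protocol import StimulusConfig, TrialKind, TrialSpec


@pytest.fixture
def stim() -> StimulusConfig:
    return StimulusConfig()


@pytest.fixture
def detcfg() -> DetectionConfig:
    return DetectionConfig()


@pytest.fixture
def cs_plus_trial(stim) -> TrialSpec:
    return TrialSpec(
        index=0,
        kind=TrialKind.CS_PLUS,
        iti_before=20.0,
        cs_onset=stim.cs_onset_in_trace,
        us_onset=stim.us_onset_in_trace,
    )


@pytest.fixture
def cs_minus_trial(stim) -> TrialSpec:
    return TrialSpec(
        index=1,
        kind=TrialKind.CS_MINUS,
        iti_before=20.0,
        cs_onset=stim.cs_onset_in_trace,
        us_onset=None,
    )


@pytest.fixture
def us_alone_trial(stim) -> TrialSpec:
    return TrialSpec(
        index=2,
        kind=TrialKind.US_ALONE,
        iti_before=20.0,
        cs_onset=None,
        us_onset=stim.us_onset_in_trace,
    )


def gaussian_bump(n: int, peak_ms: float, amp: float, fwhm_ms: float = 40.0):
    """Smooth unimodal envelope used to construct detector inputs."""
    t = np.arange(n, dtype=float)
    sigma = fwhm_ms / 2.35482
    return amp * np.exp(-0.5 * ((t - peak_ms) / sigma) ** 2)
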