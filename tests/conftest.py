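"""Shared fixtures: closed-form kinematic pulses and simulated recordings."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.stats import beta as beta_dist

from reachkin.segmentation import SubmovementWindow
from reachkin.signals import KinematicTrace, differentiate

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def closed_form_pulse(
    A: float = 29.0,
    T: float = 1.5,
    shape: tuple[float, float] = (3.0, 3.0),
    fs: float = 1000.0,
    dwell: float = 1.0,
    x0: float = 90.0,
    channel: str = "horizontal",
) -> tuple[KinematicTrace, SubmovementWindow]:
    """One noiseless Beta-profile submovement sampled directly at ``fs``.

    The trace is built by exact evaluation of the closed-form trajectory and
    forward-Euler differentiation (no filtering); the window spans the
    nominal movement bounds. Shape (3, 3) is the minimum-jerk pulse.
    """
    n = int(round((2 * dwell + T) * fs))
    t = np.arange(n + 1) / fs
    tau = np.clip((t - dwell) / T, 0.0, 1.0)
    x = x0 + A * beta_dist.cdf(tau, *shape)
    v = differentiate(t, x)
    a = differentiate(t, v)
    j = differentiate(t, a)
    trace = KinematicTrace(channel=channel, fs=fs, t=t, x=x, v=v, a=a, j=j)
    onset_i = int(round(dwell * fs))
    offset_i = int(round((dwell + T) * fs))
    mode = (shape[0] - 1.0) / (shape[0] + shape[1] - 2.0)
    peak_i = int(round((dwell + mode * T) * fs))
    window = SubmovementWindow(
        channel=channel,
        phase_id=1,
        onset_i=onset_i,
        peak_i=peak_i,
        offset_i=offset_i,
        onset_t=float(t[onset_i]),
        peak_t=float(t[peak_i]),
        offset_t=float(t[offset_i]),
        direction=1 if A >= 0 else -1,
    )
    return trace, window


@pytest.fixture(scope="session")
def minjerk_pulse() -> tuple[KinematicTrace, SubmovementWindow]:
    """Canonical minimum-jerk submovement: 29 degrees in 1.5 s at 1 kHz."""
    return closed_form_pulse()


@pytest.fixture(scope="session")
def healthy_processed():
    """A preprocessed, segmented healthy recording (shared, read-only)."""
    from reachkin import SubjectProfile, generate_recording, preprocess, segment_recording

    rec, truth = generate_recording(SubjectProfile.healthy(), seed=42, subject_id="H1")
    traces = preprocess(rec)
    windows = segment_recording(traces)
    return rec, truth, traces, windows


@pytest.fixture(scope="session")
def parkinson_processed():
    """A preprocessed, segmented Parkinson-like recording (shared, read-only)."""
    from reachkin import SubjectProfile, generate_recording, preprocess, segment_recording

    rec, truth = generate_recording(SubjectProfile.parkinson(), seed=43, subject_id="P1")
    traces = preprocess(rec)
    windows = segment_recording(traces)
    return rec, truth, traces, windows
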