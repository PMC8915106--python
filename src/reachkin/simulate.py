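"""Synthetic two-channel goniometric recordings with ground truth.

The generator emulates the eight-phase reaching protocol: starting from a
middle position, the arm visits outer-right, top, outer-left and bottom
targets and returns after each, alternating shoulder extension/flexion on
the horizontal channel (phases 1, 2, 5, 6) with elevation/lowering on the
vertical channel (phases 3, 4, 7, 8), separated by dwell periods.

Each phase is a point-to-point movement whose velocity profile is a Beta
density in normalised time. Shape (3, 3) is exactly the minimum-jerk bell
(the position is the quintic 10 tau^3 - 15 tau^4 + 6 tau^5), the model of
healthy reaching; right-skewed shapes such as (2.5, 4.5) give the prolonged
deceleration typical of bradykinesia. The Parkinson-like profile further
slows every phase (duration scale 2.2), superimposes a 5 Hz tremor
sinusoid, and is generated with the same additive sensor noise as the
healthy profile. Output is sampled at the goniometer's nominal 20 Hz so the
analysis pipeline must exercise its full resampling path.

Ground-truth onset/offset times use the standard motor-control convention:
the crossings of 5% of the phase's peak velocity on the noiseless
generative profile. The nominal phase bounds (where the generative velocity
is identically zero) are recorded alongside.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import beta as beta_dist

from .errors import ParameterError
from .segmentation import PROTOCOL_PHASES
from .signals import HORIZONTAL_COL, TIME_COL, VERTICAL_COL, Recording

__all__ = [
    "SubjectProfile",
    "GroundTruthPhase",
    "GroundTruth",
    "minimum_jerk",
    "beta_profile_movement",
    "generate_recording",
    "generate_cohort",
    "write_recording",
    "write_cohort",
]


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of one simulated subject group.

    ``duration_scale`` multiplies the base phase duration (bradykinetic
    slowing); ``velocity_profile_shape`` are the Beta density parameters of
    the velocity bell; ``tremor_amp``/``tremor_freq`` describe a sinusoid
    added to both channels throughout; ``noise_sd`` is white sensor noise
    per sample; ``between_subject_sd`` is the log-scale spread of the
    multiplicative per-subject factors on duration, amplitude and tremor;
    ``phase_jitter_sd`` the within-recording spread across phases.
    """

    group: str = "healthy"
    duration_scale: float = 1.0
    velocity_profile_shape: tuple[float, float] = (3.0, 3.0)
    tremor_freq: float = 5.0
    tremor_amp: float = 0.0
    noise_sd: float = 0.1
    dwell: float = 1.0
    amplitude_deg: float = 29.0
    base_duration: float = 1.5
    middle_deg: float = 90.0
    between_subject_sd: float = 0.08
    phase_jitter_sd: float = 0.03
    fs_raw: float = 20.0

    def __post_init__(self) -> None:
        a, b = self.velocity_profile_shape
        if a <= 1.0 or b <= 1.0:
            raise ParameterError(
                "Beta shape parameters must exceed 1 (velocity must vanish at the endpoints)"
            )
        for name in ("duration_scale", "dwell", "amplitude_deg", "base_duration", "fs_raw"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")

    @classmethod
    def healthy(cls, **overrides) -> "SubjectProfile":
        return cls(group="healthy", **overrides)

    @classmethod
    def parkinson(cls, **overrides) -> "SubjectProfile":
        """Slow, asymmetric, tremulous motion profile."""
        defaults = dict(
            group="parkinson",
            duration_scale=2.2,
            velocity_profile_shape=(2.5, 4.5),
            tremor_amp=1.5,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class GroundTruthPhase:
    """True timing and generative parameters of one protocol phase."""

    phase_id: int
    channel: str
    direction: int
    onset_t: float  # 5%-of-peak-velocity crossing
    offset_t: float
    peak_t: float  # time of the velocity-profile mode
    onset_nominal: float  # where the generative velocity is exactly zero
    offset_nominal: float
    amplitude: float
    duration: float
    shape: tuple[float, float]


@dataclass
class GroundTruth:
    """Per-recording annotation emitted next to the signal."""

    seed: int
    profile: SubjectProfile
    phases: list[GroundTruthPhase] = field(default_factory=list)

    def phases_on(self, channel: str) -> list[GroundTruthPhase]:
        return sorted(
            (p for p in self.phases if p.channel == channel), key=lambda p: p.onset_t
        )


def minimum_jerk(
    x0: float, xf: float, T: float, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-jerk point-to-point trajectory sampled at ``fs``.

    ``x(tau) = x0 + (xf - x0) (10 tau^3 - 15 tau^4 + 6 tau^5)`` with
    ``tau = t/T``: the quintic that moves from rest to rest with minimal
    integrated squared jerk. Peak velocity is ``1.875 (xf - x0) / T``.
    """
    if T <= 0:
        raise ParameterError(f"movement time must be positive, got {T}")
    t = np.arange(int(round(T * fs)) + 1) / fs
    tau = np.clip(t / T, 0.0, 1.0)
    x = x0 + (xf - x0) * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    return t, x


def beta_profile_movement(
    x0: float,
    xf: float,
    T: float,
    shape: tuple[float, float],
    fs: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Point-to-point movement whose velocity is a Beta(a, b) bell.

    The position is ``x0 + (xf - x0) I(t/T; a, b)`` with ``I`` the
    regularised incomplete beta function, so the net displacement is exact.
    Shape (3, 3) reproduces :func:`minimum_jerk` identically.
    """
    if T <= 0:
        raise ParameterError(f"movement time must be positive, got {T}")
    a, b = shape
    if a <= 1.0 or b <= 1.0:
        raise ParameterError("Beta shape parameters must exceed 1")
    t = np.arange(int(round(T * fs)) + 1) / fs
    tau = np.clip(t / T, 0.0, 1.0)
    x = x0 + (xf - x0) * beta_dist.cdf(tau, a, b)
    return t, x


def _velocity_support(shape: tuple[float, float], frac: float = 0.05) -> tuple[float, float]:
    """Normalised times where the Beta velocity bell crosses ``frac`` of its peak."""
    a, b = shape
    mode = (a - 1.0) / (a + b - 2.0)
    peak = beta_dist.pdf(mode, a, b)
    f = lambda tau: beta_dist.pdf(tau, a, b) - frac * peak
    lo = brentq(f, 1e-9, mode)
    hi = brentq(f, mode, 1.0 - 1e-9)
    return lo, hi


def _subject_factors(profile: SubjectProfile, rng: np.random.Generator) -> dict[str, float]:
    sd = profile.between_subject_sd
    return {
        "duration": float(np.exp(rng.normal(0.0, sd))),
        "amplitude": float(np.exp(rng.normal(0.0, sd))),
        "tremor": float(np.exp(rng.normal(0.0, sd))),
    }


def generate_recording(
    profile: SubjectProfile,
    seed: int,
    subject_id: str = "sim",
    trial: int = 1,
    subject_factors: dict[str, float] | None = None,
) -> tuple[Recording, GroundTruth]:
    """One full eight-phase recording plus its ground truth.

    Deterministic given ``seed``. ``subject_factors`` (as drawn by
    :func:`generate_cohort`) carry the between-subject variability shared
    across a subject's trials; when absent they are drawn here.
    """
    rng = np.random.default_rng(seed)
    factors = subject_factors if subject_factors is not None else _subject_factors(profile, rng)

    # per-phase schedule
    events = []
    t_cursor = profile.dwell
    for phase_id, channel, sign in PROTOCOL_PHASES:
        T = (
            profile.base_duration
            * profile.duration_scale
            * factors["duration"]
            * float(np.exp(rng.normal(0.0, profile.phase_jitter_sd)))
        )
        A = (
            profile.amplitude_deg
            * factors["amplitude"]
            * float(np.exp(rng.normal(0.0, profile.phase_jitter_sd)))
        )
        events.append((phase_id, channel, sign, t_cursor, T, A))
        t_cursor += T + profile.dwell

    total = t_cursor + profile.dwell
    fs = profile.fs_raw
    t = np.arange(int(np.floor(total * fs)) + 1) / fs
    pos = {
        "horizontal": np.full(len(t), profile.middle_deg),
        "vertical": np.full(len(t), profile.middle_deg),
    }
    shape = profile.velocity_profile_shape
    lo5, hi5 = _velocity_support(shape)
    mode = (shape[0] - 1.0) / (shape[0] + shape[1] - 2.0)

    truth = GroundTruth(seed=seed, profile=profile)
    for phase_id, channel, sign, ts, T, A in events:
        tau = np.clip((t - ts) / T, 0.0, 1.0)
        pos[channel] = pos[channel] + sign * A * beta_dist.cdf(tau, *shape)
        truth.phases.append(
            GroundTruthPhase(
                phase_id=phase_id,
                channel=channel,
                direction=sign,
                onset_t=ts + lo5 * T,
                offset_t=ts + hi5 * T,
                peak_t=ts + mode * T,
                onset_nominal=ts,
                offset_nominal=ts + T,
                amplitude=A,
                duration=T,
                shape=shape,
            )
        )

    tremor_phase = rng.uniform(0.0, 2.0 * np.pi)
    tremor = (
        profile.tremor_amp
        * factors["tremor"]
        * np.sin(2.0 * np.pi * profile.tremor_freq * t + tremor_phase)
        if profile.tremor_amp > 0
        else 0.0
    )
    for channel in pos:
        pos[channel] = pos[channel] + tremor + rng.normal(0.0, profile.noise_sd, len(t))

    rec = Recording(
        subject_id=subject_id,
        group=profile.group,
        trial=trial,
        fs_raw=fs,
        t=t,
        horizontal=pos["horizontal"],
        vertical=pos["vertical"],
    )
    return rec, truth


def generate_cohort(
    n_per_group: int,
    trials: int = 2,
    seed: int = 0,
    healthy_profile: SubjectProfile | None = None,
    parkinson_profile: SubjectProfile | None = None,
) -> list[tuple[Recording, GroundTruth]]:
    """A two-group cohort: ``n_per_group`` subjects per group, ``trials`` each.

    Subject-level parameter draws are shared across that subject's trials;
    the whole cohort is deterministic given ``seed``. The default design
    (six subjects per group, two trials) yields 24 recordings.
    """
    if n_per_group < 1 or trials < 1:
        raise ParameterError("n_per_group and trials must be >= 1")
    healthy_profile = healthy_profile or SubjectProfile.healthy()
    parkinson_profile = parkinson_profile or SubjectProfile.parkinson()
    rng = np.random.default_rng(seed)
    out: list[tuple[Recording, GroundTruth]] = []
    for profile, prefix in ((healthy_profile, "H"), (parkinson_profile, "P")):
        for s in range(n_per_group):
            factors = _subject_factors(profile, rng)
            subject_id = f"{prefix}{s + 1:02d}"
            for trial in range(1, trials + 1):
                child = int(rng.integers(2**31))
                out.append(
                    generate_recording(
                        profile, child, subject_id=subject_id, trial=trial,
                        subject_factors=factors,
                    )
                )
    return out


def write_recording(
    rec: Recording, truth: GroundTruth, out_dir: str | Path, precision: int = 6
) -> Path:
    """Write one recording as CSV plus a ground-truth JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{rec.subject_id}_trial{rec.trial}"
    csv_path = out_dir / f"{stem}.csv"
    pd.DataFrame(
        {TIME_COL: rec.t, HORIZONTAL_COL: rec.horizontal, VERTICAL_COL: rec.vertical}
    ).to_csv(csv_path, index=False, float_format=f"%.{precision}g")
    sidecar = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "trial": rec.trial,
        "seed": truth.seed,
        "profile": dataclasses.asdict(truth.profile),
        "phases": [dataclasses.asdict(p) for p in truth.phases],
    }
    (out_dir / f"{stem}.truth.json").write_text(json.dumps(sidecar, indent=1))
    return csv_path


def write_cohort(
    cohort: list[tuple[Recording, GroundTruth]], out_dir: str | Path
) -> pd.DataFrame:
    """Write a cohort and return its manifest (also saved as manifest.csv)."""
    rows = []
    for rec, truth in cohort:
        path = write_recording(rec, truth, out_dir)
        rows.append(
            {
                "path": path.name,
                "subject": rec.subject_id,
                "group": rec.group,
                "trial": rec.trial,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return manifest
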