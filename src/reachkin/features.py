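"""Kinematic parameters of a submovement.

Thirteen parameters are computed over each detected window:

===============  =========  =====================================================
parameter        units      definition
===============  =========  =====================================================
amplitude        deg        |x(offset) - x(onset)|
duration         s          offset_t - onset_t
v_mean           deg/s      amplitude / duration
v_max            deg/s      max |v| over the window
a_max            deg/s^2    max |a| over the window
jerk_max         deg/s^3    max |J| over the window
symmetry         --         deceleration time / acceleration time, split at the
                            |v| peak
p_mean           deg        mean of the position samples
p_root_mean      deg^2      mean of the squared position samples
variance         deg^2      variance of the position samples
skewness         --         3rd standardized moment of time under the density
                            p(t) proportional to |v(t)| (velocity-profile shape)
kurtosis         --         4th standardized moment of the same density,
                            non-excess (a minimum-jerk bell gives 7/3)
smoothness       deg/s^2    integral of |jerk| over the window (higher = rougher)
===============  =========  =====================================================

The shape moments treat the rectified velocity profile as an (unnormalised)
probability density over time, so they measure the profile's form — a
prolonged deceleration phase yields positive skewness — independently of
movement amplitude and timing. A dimensionless smoothness variant
``sqrt(T^5 / A^2 * integral(J^2))`` (the normalised jerk cost, minimised at
sqrt(720) by the minimum-jerk trajectory) is available through the config.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .segmentation import SubmovementWindow
from .signals import KinematicTrace

__all__ = [
    "PARAMETERS",
    "FeatureConfig",
    "FeatureVector",
    "basic_features",
    "symmetry_coefficient",
    "morphology_moments",
    "smoothness",
    "extract_features",
    "features_table",
    "average_features",
]

PARAMETERS = (
    "amplitude",
    "duration",
    "v_mean",
    "v_max",
    "a_max",
    "jerk_max",
    "symmetry",
    "p_mean",
    "p_root_mean",
    "variance",
    "skewness",
    "kurtosis",
    "smoothness",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction options.

    ``smoothness_metric``: ``"jerk_integral"`` (integral of |J|, the default)
    or ``"dimensionless"`` (amplitude- and duration-normalised jerk cost).
    ``moment_basis``: ``"velocity_weighted_time"`` (default; shape of the
    velocity profile) or ``"position"`` (moments of the raw position
    samples) for skewness/kurtosis.
    ``min_phases``: minimum number of phases required to average a recording.
    """

    smoothness_metric: str = "jerk_integral"
    moment_basis: str = "velocity_weighted_time"
    min_phases: int = 6

    def __post_init__(self) -> None:
        if self.smoothness_metric not in ("jerk_integral", "dimensionless"):
            raise ParameterError(f"unknown smoothness metric {self.smoothness_metric!r}")
        if self.moment_basis not in ("velocity_weighted_time", "position"):
            raise ParameterError(f"unknown moment basis {self.moment_basis!r}")
        if self.min_phases < 1:
            raise ParameterError("min_phases must be >= 1")


@dataclass
class FeatureVector:
    amplitude: float
    duration: float
    v_mean: float
    v_max: float
    a_max: float
    jerk_max: float
    symmetry: float
    p_mean: float
    p_root_mean: float
    variance: float
    skewness: float
    kurtosis: float
    smoothness: float

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def _window_slice(trace: KinematicTrace, w: SubmovementWindow) -> slice:
    if not (0 <= w.onset_i < w.offset_i < len(trace.t)):
        raise ValidationError("window does not lie within the trace")
    return slice(w.onset_i, w.offset_i + 1)


def basic_features(trace: KinematicTrace, w: SubmovementWindow) -> dict[str, float]:
    """Amplitude, duration, mean/max velocity, max acceleration, max jerk.

    Extrema are taken on absolute values so phases of either direction
    report positive magnitudes.
    """
    s = _window_slice(trace, w)
    duration = w.offset_t - w.onset_t
    if duration <= 0:
        raise ValidationError("window duration must be positive")
    amplitude = abs(float(trace.x[w.offset_i] - trace.x[w.onset_i]))
    if amplitude == 0.0:
        raise ValidationError("window has zero net displacement (static window)")
    return {
        "amplitude": amplitude,
        "duration": duration,
        "v_mean": amplitude / duration,
        "v_max": float(np.max(np.abs(trace.v[s]))),
        "a_max": float(np.max(np.abs(trace.a[s]))),
        "jerk_max": float(np.max(np.abs(trace.j[s]))),
    }


def symmetry_coefficient(trace: KinematicTrace, w: SubmovementWindow) -> float:
    """Deceleration-to-acceleration duration ratio, split at the |v| peak.

    1 for a symmetric bell; > 1 when the deceleration phase is prolonged,
    as is typical of bradykinetic movements.
    """
    s = _window_slice(trace, w)
    peak_i = w.onset_i + int(np.argmax(np.abs(trace.v[s])))
    if peak_i <= w.onset_i or peak_i >= w.offset_i:
        raise ValidationError("velocity peak at window edge: degenerate window")
    t = trace.t
    return float((t[w.offset_i] - t[peak_i]) / (t[peak_i] - t[w.onset_i]))


def morphology_moments(
    trace: KinematicTrace,
    w: SubmovementWindow,
    cfg: FeatureConfig = FeatureConfig(),
) -> dict[str, float]:
    """Location, scale and shape statistics of the submovement.

    Location/scale (``p_mean``, ``p_root_mean``, ``variance``) are computed
    on the position samples. Shape (``skewness``, ``kurtosis``) is computed
    on time weighted by |v| — the velocity profile read as a density — so a
    symmetric bell scores skewness 0 and kurtosis 7/3, regardless of
    amplitude or duration. With ``moment_basis="position"`` the shape
    moments are instead those of the position samples.
    """
    s = _window_slice(trace, w)
    if w.n_samples < 10:
        raise ValidationError("window too short for moment estimation (< 10 samples)")
    x = trace.x[s]
    out = {
        "p_mean": float(np.mean(x)),
        "p_root_mean": float(np.mean(x**2)),
        "variance": float(np.var(x)),
    }
    if cfg.moment_basis == "position":
        sd = np.std(x)
        if sd == 0:
            raise ValidationError("zero position variance: shape moments undefined")
        z = (x - np.mean(x)) / sd
        out["skewness"] = float(np.mean(z**3))
        out["kurtosis"] = float(np.mean(z**4))
        return out
    av = np.abs(trace.v[s])
    total = float(np.sum(av))
    if total == 0.0:
        raise ValidationError("zero velocity over the window: shape moments undefined")
    p = av / total
    t = trace.t[s]
    mu = float(np.sum(p * t))
    var = float(np.sum(p * (t - mu) ** 2))
    if var == 0.0:
        raise ValidationError("degenerate velocity profile: zero time variance")
    out["skewness"] = float(np.sum(p * (t - mu) ** 3) / var**1.5)
    out["kurtosis"] = float(np.sum(p * (t - mu) ** 4) / var**2)
    return out


def smoothness(
    trace: KinematicTrace,
    w: SubmovementWindow,
    cfg: FeatureConfig = FeatureConfig(),
) -> float:
    """Jerk-based roughness of the submovement.

    Default: rectangle-rule integral of |J(t)| over the window (deg/s^2);
    equals four times the acceleration extremum for a clean minimum-jerk
    pulse and grows with any superimposed oscillation. The dimensionless
    variant ``sqrt(T^5/A^2 * integral(J^2))`` has minimum ``sqrt(720)``
    (the quintic's exact jerk cost), attained by the minimum-jerk
    trajectory.
    """
    s = _window_slice(trace, w)
    dt = 1.0 / trace.fs
    j = trace.j[s]
    if cfg.smoothness_metric == "jerk_integral":
        return float(np.sum(np.abs(j)) * dt)
    duration = w.offset_t - w.onset_t
    amplitude = abs(float(trace.x[w.offset_i] - trace.x[w.onset_i]))
    if amplitude == 0.0:
        raise ValidationError("zero amplitude: dimensionless jerk undefined")
    return float(np.sqrt(duration**5 / amplitude**2 * np.sum(j**2) * dt))


def extract_features(
    trace: KinematicTrace,
    w: SubmovementWindow,
    cfg: FeatureConfig = FeatureConfig(),
) -> FeatureVector:
    """All thirteen parameters of one submovement window."""
    vals = basic_features(trace, w)
    vals["symmetry"] = symmetry_coefficient(trace, w)
    vals.update(morphology_moments(trace, w, cfg))
    vals["smoothness"] = smoothness(trace, w, cfg)
    return FeatureVector(**vals)


def features_table(
    traces: tuple[KinematicTrace, KinematicTrace],
    windows: list[SubmovementWindow],
    subject_id: str = "unknown",
    group: str = "healthy",
    trial: int = 1,
    cfg: FeatureConfig = FeatureConfig(),
) -> pd.DataFrame:
    """Tidy table: one row per submovement window with the 13 parameters."""
    by_channel = {tr.channel: tr for tr in traces}
    rows = []
    for w in windows:
        fv = extract_features(by_channel[w.channel], w, cfg)
        rows.append(
            {
                "subject": subject_id,
                "group": group,
                "trial": trial,
                "channel": w.channel,
                "phase_id": w.phase_id,
                **fv.to_dict(),
            }
        )
    return pd.DataFrame(rows)


def average_features(
    per_phase: list[FeatureVector] | pd.DataFrame,
    cfg: FeatureConfig = FeatureConfig(),
) -> tuple[FeatureVector, bool]:
    """Arithmetic mean of each parameter over the submovements of a recording.

    The full protocol has eight phases; averaging proceeds when at least
    ``cfg.min_phases`` are present, in which case the second return value
    flags that phases were missing.
    """
    if isinstance(per_phase, pd.DataFrame):
        vectors = [
            FeatureVector(**{p: float(row[p]) for p in PARAMETERS})
            for _, row in per_phase.iterrows()
        ]
    else:
        vectors = list(per_phase)
    n = len(vectors)
    if n < cfg.min_phases:
        raise ValidationError(
            f"only {n} phases present; at least {cfg.min_phases} required to average"
        )
    means = {p: float(np.mean([getattr(v, p) for v in vectors])) for p in PARAMETERS}
    return FeatureVector(**means), n < 8
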