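"""Velocity-threshold submovement segmentation.

A submovement is detected wherever the absolute velocity of a channel rises
above 30% of that channel's peak absolute velocity. For each retained
velocity peak the onset (offset) is found by walking backward (forward)
from the threshold crossing while |v| keeps strictly decreasing and stays
above a small rest floor; the walk stops at the first local minimum of |v|
or on entering the rest region. This places onsets and offsets at the
position plateaus between movements, for unidirectional and bidirectional
phases alike.

Detected windows are labelled against the eight-phase reaching protocol:
phases 1, 2, 5, 6 live on the horizontal channel and phases 3, 4, 7, 8 on
the vertical channel; within a channel, phases are assigned in temporal
order and checked against the expected displacement direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ParameterError, ValidationError
from .signals import KinematicTrace

__all__ = [
    "SegmentationConfig",
    "SubmovementWindow",
    "compute_threshold",
    "find_velocity_peaks",
    "locate_onset_offset",
    "segment_recording",
    "windows_to_frame",
    "PROTOCOL_PHASES",
]

#: (phase_id, channel, expected direction sign) in protocol order.
#: Middle -> outer-right, back, middle -> top, back, middle -> outer-left,
#: back, middle -> bottom, back. Outward "right" and "up" are positive.
PROTOCOL_PHASES: tuple[tuple[int, str, int], ...] = (
    (1, "horizontal", +1),
    (2, "horizontal", -1),
    (3, "vertical", +1),
    (4, "vertical", -1),
    (5, "horizontal", -1),
    (6, "horizontal", +1),
    (7, "vertical", -1),
    (8, "vertical", +1),
)


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunables of the threshold segmenter.

    All fractions are relative to the channel's peak absolute velocity, so
    segmentation is invariant to amplitude scaling of the signal.

    Attributes
    ----------
    threshold_frac : detection threshold as a fraction of max |v| (0.30).
    min_peak_prominence_frac : prominence floor for peak pruning, removes
        spurious ripples (e.g. residual tremor) riding on a movement.
    min_peak_separation : minimum time between retained peaks, seconds.
    velocity_floor_frac : |v| below this fraction of max |v| counts as rest
        when locating onsets/offsets.
    phase_map : protocol table used for labelling; override for recordings
        acquired with a different task order.
    """

    threshold_frac: float = 0.30
    min_peak_prominence_frac: float = 0.10
    min_peak_separation: float = 0.5
    velocity_floor_frac: float = 0.05
    phase_map: tuple[tuple[int, str, int], ...] = PROTOCOL_PHASES

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_frac < 1.0:
            raise ParameterError("threshold_frac must lie in (0, 1)")
        if not 0.0 <= self.velocity_floor_frac < self.threshold_frac:
            raise ParameterError("velocity_floor_frac must be below threshold_frac")
        if self.min_peak_separation < 0:
            raise ParameterError("min_peak_separation must be non-negative")


@dataclass
class SubmovementWindow:
    """One detected submovement on one channel.

    ``phase_id`` refers to the eight-phase protocol (0 when unlabelled);
    ``direction`` is the sign of the net angular displacement over the
    window; ``boundary_flag`` marks windows clipped at the signal edge.
    """

    channel: str
    phase_id: int
    onset_i: int
    peak_i: int
    offset_i: int
    onset_t: float
    peak_t: float
    offset_t: float
    direction: int
    boundary_flag: bool = False

    def __post_init__(self) -> None:
        if not self.onset_i <= self.peak_i <= self.offset_i:
            raise ValidationError("window indices must satisfy onset <= peak <= offset")

    @property
    def duration(self) -> float:
        return self.offset_t - self.onset_t

    @property
    def n_samples(self) -> int:
        return self.offset_i - self.onset_i + 1


def compute_threshold(v: np.ndarray, cfg: SegmentationConfig = SegmentationConfig()) -> float:
    """Detection threshold: ``threshold_frac`` times the peak of |v|."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValidationError("velocity array is empty")
    return cfg.threshold_frac * float(np.max(np.abs(v)))


def find_velocity_peaks(
    v: np.ndarray, t: np.ndarray, cfg: SegmentationConfig = SegmentationConfig()
) -> np.ndarray:
    """Local maxima of |v| above threshold, pruned by prominence and separation.

    The prominence floor (fraction of max |v|) removes spurious ripples such
    as residual tremor superimposed on a voluntary movement; the separation
    constraint keeps one peak per submovement. Returns indices in time order.
    """
    v = np.asarray(v, dtype=float)
    t = np.asarray(t, dtype=float)
    av = np.abs(v)
    vmax = float(np.max(av)) if av.size else 0.0
    if vmax == 0.0:
        return np.array([], dtype=int)
    thr = cfg.threshold_frac * vmax
    fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    distance = max(1, int(round(cfg.min_peak_separation * fs)))
    peaks, _ = find_peaks(
        av,
        height=thr,
        prominence=cfg.min_peak_prominence_frac * vmax,
        distance=distance,
    )
    return peaks


def _walk(av: np.ndarray, start: int, step: int, threshold: float, floor: float) -> int:
    """Walk from the threshold crossing to the nearest rest point.

    First leave the supra-threshold region, then continue while |v| is
    strictly decreasing and above the rest floor. Stops at the first local
    minimum of |v| or the first sample at/below the floor.
    """
    n = len(av)
    i = start
    while 0 <= i + step < n and av[i + step] >= threshold:
        i += step
    while 0 <= i + step < n and av[i + step] < av[i] and av[i] > floor:
        i += step
    return i


def locate_onset_offset(
    v: np.ndarray,
    t: np.ndarray,
    peak_i: int,
    threshold: float,
    cfg: SegmentationConfig = SegmentationConfig(),
) -> tuple[int, int, bool]:
    """Onset and offset sample indices for the submovement around ``peak_i``.

    Returns ``(onset_i, offset_i, boundary_flag)``; the flag is set when the
    window is clipped at a signal edge while |v| is still above threshold.
    """
    v = np.asarray(v, dtype=float)
    av = np.abs(v)
    if av[peak_i] <= threshold:
        raise ValidationError("peak sample is not above the detection threshold")
    floor = cfg.velocity_floor_frac * float(np.max(av))
    onset = _walk(av, peak_i, -1, threshold, floor)
    offset = _walk(av, peak_i, +1, threshold, floor)
    clipped = (onset == 0 and av[0] >= threshold) or (
        offset == len(av) - 1 and av[-1] >= threshold
    )
    return onset, offset, clipped


def _resolve_overlaps(av: np.ndarray, wins: list[SubmovementWindow], t: np.ndarray) -> None:
    """Truncate overlapping adjacent windows at the inter-peak |v| valley."""
    for w1, w2 in zip(wins, wins[1:]):
        if w1.offset_i > w2.onset_i:
            valley = w1.peak_i + int(np.argmin(av[w1.peak_i : w2.peak_i + 1]))
            w1.offset_i = valley
            w1.offset_t = float(t[valley])
            w2.onset_i = valley
            w2.onset_t = float(t[valley])


def _segment_channel(
    trace: KinematicTrace, cfg: SegmentationConfig
) -> list[SubmovementWindow]:
    av = np.abs(trace.v)
    if float(np.max(av, initial=0.0)) == 0.0:
        return []
    threshold = compute_threshold(trace.v, cfg)
    peaks = find_velocity_peaks(trace.v, trace.t, cfg)
    wins: list[SubmovementWindow] = []
    for p in peaks:
        onset, offset, clipped = locate_onset_offset(trace.v, trace.t, int(p), threshold, cfg)
        direction = int(np.sign(trace.x[offset] - trace.x[onset])) or 1
        wins.append(
            SubmovementWindow(
                channel=trace.channel,
                phase_id=0,
                onset_i=onset,
                peak_i=int(p),
                offset_i=offset,
                onset_t=float(trace.t[onset]),
                peak_t=float(trace.t[p]),
                offset_t=float(trace.t[offset]),
                direction=direction,
                boundary_flag=clipped,
            )
        )
    _resolve_overlaps(av, wins, trace.t)
    return wins


def _label_phases(wins: list[SubmovementWindow], cfg: SegmentationConfig) -> None:
    """Assign protocol phase ids per channel, in temporal order.

    When the detected count matches the protocol (four per channel), the
    phase sequence of the protocol table is applied and displacement
    directions are checked; on a count mismatch the labelling falls back to
    ordinal assignment within the channel and emits a warning.
    """
    for channel in ("horizontal", "vertical"):
        expected = [(pid, sign) for pid, ch, sign in cfg.phase_map if ch == channel]
        ch_wins = sorted(
            (w for w in wins if w.channel == channel), key=lambda w: w.onset_t
        )
        if not ch_wins:
            if expected:
                warnings.warn(
                    f"no submovements detected on the {channel} channel "
                    f"(protocol expects {len(expected)})",
                    stacklevel=3,
                )
            continue
        if len(ch_wins) != len(expected):
            warnings.warn(
                f"{channel} channel: detected {len(ch_wins)} submovements, "
                f"protocol expects {len(expected)}; falling back to ordinal phase ids",
                stacklevel=3,
            )
            for k, w in enumerate(ch_wins):
                w.phase_id = expected[k][0] if k < len(expected) else 0
            continue
        for w, (pid, sign) in zip(ch_wins, expected):
            w.phase_id = pid
            if w.direction != sign:
                warnings.warn(
                    f"phase {pid} ({channel}): displacement direction "
                    f"{w.direction:+d} does not match protocol {sign:+d}",
                    stacklevel=3,
                )


def segment_recording(
    traces: tuple[KinematicTrace, KinematicTrace],
    cfg: SegmentationConfig = SegmentationConfig(),
) -> list[SubmovementWindow]:
    """Segment both channels of a preprocessed recording.

    Returns all detected submovement windows, phase-labelled against the
    protocol and sorted by onset time.
    """
    wins: list[SubmovementWindow] = []
    for trace in traces:
        wins.extend(_segment_channel(trace, cfg))
    _label_phases(wins, cfg)
    return sorted(wins, key=lambda w: w.onset_t)


def windows_to_frame(
    windows: list[SubmovementWindow],
    subject_id: str = "unknown",
    trial: int = 1,
) -> pd.DataFrame:
    """Tabulate windows for CSV export."""
    return pd.DataFrame(
        [
            {
                "subject": subject_id,
                "trial": trial,
                "channel": w.channel,
                "phase_id": w.phase_id,
                "onset_s": w.onset_t,
                "offset_s": w.offset_t,
                "peak_s": w.peak_t,
                "direction": w.direction,
                "boundary_flag": w.boundary_flag,
            }
            for w in windows
        ]
    )
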