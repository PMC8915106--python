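"""End-to-end pipeline: recordings in, features + statistics + heatmap out.

For each manifest entry the recording is preprocessed, segmented and
feature-extracted; the per-submovement rows are pooled, phase-averaged per
recording, and passed to the statistical layer. Artifacts written to the
output directory:

* ``features.csv`` — one row per recording x submovement (13 parameters),
* ``features_averaged.csv`` — one row per recording (phase means),
* ``windows.csv`` — detected submovement windows,
* ``stats.csv`` — descriptives, chosen test and p-value per comparison,
* ``pvalue_heatmap.csv`` — parameter x phase significance bins,
* ``run_log.txt`` — package/library versions, config echo, skips.

Recordings that fail validation are skipped with a logged reason; the run
fails only if no recording survives. Floating-point output is rounded to a
declared number of significant digits so identical runs produce
byte-identical artifacts.
"""

from __future__ import annotations

import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .config import RunConfig
from .errors import ReachkinError, ValidationError
from .features import features_table
from .gstats import analyze_feature_table, pvalue_heatmap_table, results_to_frame
from .segmentation import segment_recording, windows_to_frame
from .signals import KinematicTrace, Recording, preprocess, read_recording

__all__ = [
    "process_recording",
    "run_pipeline",
    "write_traces",
    "read_traces",
]


def write_traces(
    traces: tuple[KinematicTrace, KinematicTrace],
    path: str | Path,
    precision: int = 6,
) -> Path:
    """Persist preprocessed traces as a long-format CSV (one row per sample)."""
    path = Path(path)
    frames = [
        pd.DataFrame(
            {
                "channel": tr.channel,
                "time_s": tr.t,
                "x_deg": tr.x,
                "v_degs": tr.v,
                "a_degs2": tr.a,
                "j_degs3": tr.j,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=f"%.{precision}g"
    )
    return path


def read_traces(path: str | Path) -> tuple[KinematicTrace, KinematicTrace]:
    """Load traces written by :func:`write_traces`."""
    df = pd.read_csv(path)
    out = []
    for channel in ("horizontal", "vertical"):
        sub = df[df["channel"] == channel]
        if sub.empty:
            raise ValidationError(f"{path}: no rows for channel {channel!r}")
        t = sub["time_s"].to_numpy()
        fs = 1.0 / float(np.median(np.diff(t)))
        out.append(
            KinematicTrace(
                channel=channel,
                fs=fs,
                t=t,
                x=sub["x_deg"].to_numpy(),
                v=sub["v_degs"].to_numpy(),
                a=sub["a_degs2"].to_numpy(),
                j=sub["j_degs3"].to_numpy(),
            )
        )
    return out[0], out[1]


def process_recording(
    rec: Recording, cfg: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Preprocess, segment and extract one recording.

    Returns ``(features, windows)`` tidy tables for this recording.
    """
    traces = preprocess(
        rec,
        spec=cfg.filter,
        fs_target=cfg.fs_target,
        refilter_derivatives=cfg.refilter_derivatives,
    )
    windows = segment_recording(traces, cfg.segmentation)
    feats = features_table(
        traces,
        windows,
        subject_id=rec.subject_id,
        group=rec.group,
        trial=rec.trial,
        cfg=cfg.features,
    )
    wins = windows_to_frame(windows, subject_id=rec.subject_id, trial=rec.trial)
    return feats, wins


def _averaged_frame(features: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    from .gstats import _averaged_table

    return _averaged_table(features, cfg.features.min_phases)


def run_pipeline(cfg: RunConfig, dry_run: bool = False) -> Path:
    """Run the full analysis described by ``cfg``; returns the output directory.

    With ``dry_run`` the config and manifest are validated and nothing is
    written.
    """
    if not cfg.manifest:
        raise ValidationError("config manifest is empty: nothing to process")
    missing = [e.path for e in cfg.manifest if not Path(e.path).exists()]
    if missing:
        raise ValidationError(f"manifest references missing files: {missing}")
    if dry_run:
        return Path(cfg.out_dir)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"reachkin {__version__} (numpy {np.__version__}, scipy {scipy.__version__}, "
        f"pandas {pd.__version__}, python {sys.version.split()[0]})",
        f"config: {cfg.to_dict()}",
    ]

    all_feats, all_wins = [], []
    n_ok = 0
    for entry in cfg.manifest:
        try:
            rec = read_recording(
                entry.path, subject_id=entry.subject, group=entry.group, trial=entry.trial
            )
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                feats, wins = process_recording(rec, cfg)
            for c in caught:
                log_lines.append(f"warning [{entry.path}]: {c.message}")
            all_feats.append(feats)
            all_wins.append(wins)
            n_ok += 1
        except ReachkinError as exc:
            log_lines.append(f"skipped [{entry.path}]: {exc}")
    if n_ok == 0:
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        raise ValidationError("no usable recordings in the manifest (see run_log.txt)")

    ff = cfg.float_format
    features = pd.concat(all_feats, ignore_index=True)
    features.to_csv(out / "features.csv", index=False, float_format=ff)
    pd.concat(all_wins, ignore_index=True).to_csv(
        out / "windows.csv", index=False, float_format=ff
    )
    averaged = _averaged_frame(features, cfg)
    averaged.to_csv(out / "features_averaged.csv", index=False, float_format=ff)

    if features["group"].nunique() == 2:
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                results = analyze_feature_table(features, cfg.stats, cfg.features)
            for c in caught:
                log_lines.append(f"warning [stats]: {c.message}")
            results_to_frame(results).to_csv(
                out / "stats.csv", index=False, float_format=ff
            )
            pvalue_heatmap_table(results, cfg.stats).to_csv(out / "pvalue_heatmap.csv")
        except ReachkinError as exc:
            log_lines.append(f"stats skipped: {exc}")
    else:
        log_lines.append("stats skipped: need two groups in the manifest")

    log_lines.append(f"processed {n_ok}/{len(cfg.manifest)} recordings")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out
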