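# reachkin

Kinematic analysis of upper-limb reaching tasks from goniometric angle
recordings, aimed at quantifying motor impairment — e.g. distinguishing
Parkinsonian from healthy reaching — through submovement-level kinematic
parameters. Intended for movement scientists and rehabilitation
researchers working with two-channel joint-angle time series.

## What it does

The input is a recording of horizontal and vertical shoulder angle
(degrees, nominally 20 Hz) during an eight-phase reaching protocol: from a
middle position the arm visits outer-right, top, outer-left and bottom
targets, returning after each. The pipeline:

1. **Preprocessing** — cubic-spline resampling to 1 kHz, zero-phase 5th-order
   low-pass Butterworth smoothing (cutoff 1.5 Hz), and successive
   forward-Euler differentiation to velocity v(t), acceleration a(t) and
   jerk J(t), with each derivative re-smoothed before the next
   differentiation.
2. **Segmentation** — submovements are detected where |v| exceeds
   `Threshold = 0.3 · max|v|` (per channel); spurious peaks are pruned by a
   prominence rule; each onset/offset is walked out from the threshold
   crossing to the nearest rest point. Windows are labelled against the
   protocol (phases 1, 2, 5, 6 horizontal; 3, 4, 7, 8 vertical).
3. **Features** — thirteen parameters per submovement: amplitude, duration,
   mean/max velocity, max acceleration, max jerk, symmetry coefficient
   (deceleration/acceleration time), position mean / mean square / variance,
   skewness and kurtosis of the velocity-profile shape, and a jerk-based
   smoothness index `∫|J(t)| dt`. Parameters are also averaged across the
   eight phases per recording.
4. **Statistics** — per parameter (per phase and on averages), the two
   groups are compared two-sidedly at α = 0.05 with Shapiro–Wilk-routed
   test selection: normal + homoscedastic (Levene) → Student's t, normal +
   heteroscedastic → Welch's t, otherwise exact Mann–Whitney U. Output
   includes descriptives and a parameter × phase p-value heatmap table.

The reference model for healthy point-to-point reaching is the minimum-jerk
trajectory, x(τ) = x₀ + A(10τ³ − 15τ⁴ + 6τ⁵) with τ = t/T, whose
velocity profile is the symmetric bell v(τ) ∝ τ²(1−τ)² with peak
1.875·A/T. The simulator generalises this to Beta(α, β)-density velocity
profiles — (3, 3) is exactly minimum-jerk; right-skewed shapes with longer
deceleration, slowed phases (2.2×), 5 Hz tremor and sensor noise emulate
bradykinetic movement — and emits annotated ground truth so every stage is
testable without clinical data.

## Worked example

```python
from reachkin import SubjectProfile, generate_recording, preprocess, segment_recording
from reachkin.features import features_table

rec, truth = generate_recording(SubjectProfile.parkinson(), seed=7, subject_id="P01")
traces = preprocess(rec)                 # resample, filter, differentiate
windows = segment_recording(traces)      # 8 submovement windows
feats = features_table(traces, windows, subject_id="P01", group="parkinson")
print(feats[["phase_id", "channel", "amplitude", "duration", "v_max",
             "symmetry", "skewness", "smoothness"]].round(2).to_string(index=False))
```

```
 phase_id    channel  amplitude  duration  v_max  symmetry  skewness  smoothness
        1 horizontal      29.18      2.54  19.82      1.73      0.30       78.37
        2 horizontal      29.55      2.55  20.32      1.79      0.31       82.01
        3   vertical      29.12      2.70  18.76      1.83      0.31       68.46
        4   vertical      30.01      2.64  20.53      1.86      0.34       81.21
        5 horizontal      29.68      2.64  19.53      1.70      0.31       71.39
        6 horizontal      29.55      2.54  20.09      1.66      0.29       78.54
        7   vertical      28.38      2.68  18.67      1.67      0.31       68.55
        8   vertical      27.85      2.55  18.82      1.65      0.29       74.94
```

Each row is one detected submovement. The Parkinson-like profile shows the
expected signature relative to a healthy recording (duration ≈ 1.4 s,
v_max ≈ 36 deg/s, symmetry ≈ 1.0, skewness ≈ 0): phases are about twice as
long, peak velocity is roughly halved, the deceleration phase is
prolonged (symmetry > 1.6) and the velocity profile is positively skewed.

The same pipeline runs from the shell:

```sh
reachkin simulate --n-per-group 6 --trials 2 --seed 1 --out-dir data/
reachkin run-all --manifest data/manifest.csv --out-dir results/
```

which writes `features.csv`, `features_averaged.csv`, `windows.csv`,
`stats.csv`, `pvalue_heatmap.csv` and a run log. Stage-wise subcommands
(`preprocess`, `segment`, `extract`, `stats`) chain through CSVs for
inspection or replacement of any intermediate.

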