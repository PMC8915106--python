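# Methods

This note documents the models, algorithms and numerical choices behind
`reachkin`, and what its validation on synthetic data does and does not
establish.

## Signal model and preprocessing

A recording holds two goniometric angle channels (horizontal and vertical
shoulder angle, degrees) on a shared, strictly increasing time base,
nominally 20 Hz. The nominal rate is inferred from the median time step and
must agree with a declared rate within 10% (goniometer clocks jitter);
units are degrees and seconds throughout.

Each channel is resampled to a uniform 1 kHz grid by cubic spline (dense
enough that discretisation is negligible against the 1.5 Hz signal band,
and matching the rate of EMG hardware this pipeline may later be
co-registered with), then smoothed with a zero-phase 5th-order low-pass
Butterworth filter, cutoff 1.5 Hz. Forward–backward application squares the
single-pass magnitude response |H(ω)|² = 1/(1 + ω²ⁿ) (ω = f/cutoff) and
cancels the phase, so velocity peaks stay time-locked to the raw signal;
the amplitude of a sinusoid at the cutoff is halved, not reduced by 1/√2.

Two numerical choices matter here. First, the filter runs as second-order
sections: at a normalised cutoff of 0.0015 the polynomial transfer-function
coefficients underflow toward 1e-15 and the filtered DC level is wrong by
~1e-5; sections keep the error below 1e-10. Second, the reflection padding
for the forward–backward pass spans three times the filter's effective
impulse response, max(3·(2n+1), 3·fs/cutoff) samples — padding proportional
only to the coefficient count leaves visible start-up transients. Signals
shorter than the padding are rejected rather than filtered badly.

Velocity, acceleration and jerk are successive forward-Euler differences,
v[i] = (x[i+1] − x[i])/Δt, with the last sample repeating the final
difference so all traces share one grid. By default each derivative is
re-smoothed with the same zero-phase filter before the next
differentiation: bare triple differencing at 1 kHz amplifies even 0.1°
sensor noise into a jerk trace orders of magnitude above signal. The switch
(`refilter_derivatives`) and the whole filter (`spec=None`) can be disabled,
e.g. for noiseless synthetic signals where the closed-form derivatives are
wanted unmodified. The cost of smoothing is a small bias on fast
transients: for a 1.5 s minimum-jerk pulse the filtered acceleration
extremum reads ~2–4% low and the jerk integral ~12–15% low. Group
contrasts are unaffected (both groups are filtered identically), but
absolute jerk-based values should be compared only within one filter
configuration.

## Submovement segmentation

Detection operates on the rectified velocity |v| of each channel with a
threshold at 30% of that channel's peak |v| over the whole recording (one
threshold per channel, not per submovement, because the task protocol keeps
phase amplitudes comparable). Candidate peaks are local maxima of |v| above
threshold, pruned by a prominence floor of 10% of max |v| (this removes
tremor ripple riding on a movement, which modulates |v| without creating
full-depth valleys) and a minimum separation of 0.5 s. All thresholds are
fractions of max |v|, so segmentation is exactly invariant to amplitude
scaling and time shifts.

For each retained peak, the onset is found by walking backward from the
upward threshold crossing while |v| is strictly decreasing and above a rest
floor (5% of max |v|); the walk stops at the first local minimum of |v| or
on entering the rest region. The offset walk is symmetric, forward from the
downward crossing. The rationale for the combined stop rule: on clean
signals the monotone descent runs all the way to the rest plateau, so the
detected window spans essentially the whole movement; on slow, skewed
pathological profiles, whose velocity tail creeps for hundreds of
milliseconds below any measurable level, the floor terminates the walk at
the standard motor-control movement boundary (a few percent of peak
velocity) instead of wandering into the inter-movement dwell. Windows of
adjacent peaks that overlap are truncated at the inter-peak |v| minimum;
windows clipped at a recording edge carry a boundary flag.

Detected windows are labelled against the protocol table — phases 1, 2, 5,
6 on the horizontal channel, 3, 4, 7, 8 on the vertical — in temporal
order per channel, with the sign of the net displacement checked against
the expected movement direction (outward-right and upward positive). If a
channel does not yield exactly four windows, labelling falls back to
ordinal assignment and a warning is emitted; recordings acquired with a
different task order can remap via the configurable phase table.

## Kinematic parameters

Thirteen parameters per window; extrema are taken on absolute values so
both movement directions report positive magnitudes:

- amplitude |x(offset) − x(onset)| (deg), duration (s), and their ratio
  v_mean (deg/s), which satisfies v_mean · duration = amplitude by
  construction;
- v_max, a_max, jerk_max: max |v|, |a|, |J| over the window;
- symmetry: deceleration time over acceleration time, split at the |v|
  peak; 1 for a symmetric bell, > 1 for prolonged deceleration. It is
  reported positive; sign conventions that negate it in other software are
  a display choice, not a different statistic;
- p_mean, p_root_mean, variance: mean, mean of squares, and variance of the
  position samples over the window (deg, deg², deg²);
- skewness, kurtosis: standardized 3rd and 4th moments of time under the
  density p(t) ∝ |v(t)| — the velocity profile read as a distribution over
  time. This basis makes the two shape parameters dimensionless and
  invariant to amplitude scaling and time shifts, and gives clean reference
  values: a minimum-jerk bell (Beta(3,3) in normalised time) has skewness 0
  and non-excess kurtosis 7/3; a prolonged deceleration yields positive
  skew. Moments of the raw position samples are available as an alternative
  basis via configuration;
- smoothness: ∫|J(t)| dt over the window (deg/s²), the total variation of
  the acceleration — equal to 4·a_max for a clean minimum-jerk pulse and
  strictly larger under any superimposed oscillation. A dimensionless
  variant √(T⁵/A² · ∫J² dt) is available; its minimum is √720 ≈ 26.83,
  attained by the minimum-jerk trajectory (∫₀¹(60 − 360τ + 360τ²)² dτ =
  720 exactly).

Per-recording averages are the arithmetic mean of each parameter over the
phases present; averaging requires at least 6 of the 8 phases (pathological
recordings may drop one) and flags any shortfall.

## Statistical comparison

The unit of analysis defaults to one recording (a configuration option
averages trials within subject first; with two trials per subject the two
choices correspond to n = 12 or n = 6 per group). For every parameter —
per phase, and on the phase-averaged values — the two groups are compared
two-sided at α = 0.05:

1. Shapiro–Wilk normality check per group (appropriate at these sample
   sizes). A degenerate group (zero variance) fails the check by fiat.
2. Both groups normal → Levene's test (mean-centred, as in classical
   Levene) for homoscedasticity: pass → Student's t; fail → Welch's t.
3. Otherwise → Mann–Whitney U, exact when both groups have ≤ 20
   observations and no ties (at n = 6 + 6 complete separation gives
   p = 2/924 ≈ 0.0022), normal approximation with tie correction otherwise.

Results carry group descriptives (mean, SD, median, IQR), the routing
p-values, the chosen test and its p-value. The heatmap table bins p-values
at 0.05/0.10 into strong / weak / non-significant. No multiple-testing
correction is applied by default — each parameter is read as a stand-alone
candidate indicator — but Benjamini–Hochberg adjustment across the grid is
available. Calibration is verified empirically: on 500 null simulations
(n = 6 + 6) the routed procedure rejects at 4–6%.

## Synthetic recordings

The generator emulates the eight-phase protocol with per-phase
point-to-point movements whose velocity is a Beta(α, β) density in
normalised time, scaled to the phase amplitude; the position is the
regularised incomplete beta function, so displacement is exact. Shape
(3, 3) reproduces the minimum-jerk quintic identically.

Default conditions: amplitude 29° per phase, base duration 1.5 s, 1 s
dwell between phases, middle position 90°, sensor noise 0.1° per 20 Hz
sample, between-subject multiplicative variability 0.08 (log-scale) on
duration, amplitude and tremor, within-recording per-phase jitter 0.03.
The Parkinson-like profile slows phases 2.2×, skews the velocity profile to
(2.5, 4.5) (prolonged deceleration), and superimposes a 5 Hz sinusoidal
tremor of 1.5° on both channels. These settings reproduce the direction
and rough magnitude of the healthy-vs-Parkinson contrasts reported for
this class of task — longer durations, lower peak velocities, positive
skew — not any particular clinical dataset. Output is emitted at 20 Hz so
analysis must exercise its full resampling path; cohorts draw subject-level
factors once per subject, shared across that subject's trials, and are
bit-reproducible given a seed.

Ground-truth phase timing is annotated at the 5%-of-peak-velocity
crossings of the noiseless generative profile — the standard movement
onset/offset convention in motor control — because a Beta-profile velocity
approaches zero only asymptotically and no detector can recover the
nominal endpoint of an unmeasurably slow tail. The nominal bounds (where
the generative velocity is identically zero) are stored alongside.

Measured on 20 seeded recordings per group: the segmenter recovers all
8 phases in 100% of both healthy and Parkinson-like recordings, with
onset/offset errors ≤ 150 ms against the 5% convention (healthy typically
≤ 50 ms).

### What the simulation does not capture

Real goniometric recordings contain movement fragmentation (multiple
merged subpulses per phase), drift and baseline wander, variable dwell
behaviour, occasional missed or repeated phases, and tremor that is
amplitude- and frequency-modulated rather than a fixed sinusoid. Passing
tests on this generator therefore demonstrate correctness of the
algorithms under the stated motion model and robustness to stationary
tremor plus white noise — not clinical performance. The statistical layer
likewise treats recordings as independent; with two trials per subject the
default per-recording analysis understates between-subject variability.

## Problem sizes and runtime

The test suite and the acceptance script use the study-scale designs
throughout: 20 recordings per group for segmentation recovery, 6 + 6
subjects × 2 trials for the end-to-end cohorts, 500 replicates for type-I
calibration. The full suite runs in well under a minute on one CPU; the
acceptance script in a few seconds.

## Known limitations

- Jerk-magnitude features depend on the smoothing configuration (see
  preprocessing); compare them only within one configuration.
- Phase labelling assumes the canonical task order; mirrored or reordered
  acquisitions need an explicit phase-map override.
- The exact Mann–Whitney route assumes tie-free data; heavily discretised
  measurements fall back to the tie-corrected normal approximation.
- `p_root_mean` is a mean of squared positions (deg²), not a root; the
  name follows the field's customary label for this statistic.
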