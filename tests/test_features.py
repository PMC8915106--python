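"""Kinematic parameters: closed-form oracles and structural invariants.

Reference values for the minimum-jerk pulse (amplitude A, duration T):
peak velocity 1.875 A/T, peak acceleration (10/sqrt(3)) A/T^2 = 5.7735 A/T^2,
|v|-weighted time moments of the Beta(3,3) bell (skewness 0, kurtosis 7/3),
jerk integral = total variation of the acceleration = 4 a_max, and
normalised jerk cost sqrt(360).
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import beta as beta_dist

from reachkin.errors import ValidationError
from reachkin.features import (
    PARAMETERS,
    FeatureConfig,
    FeatureVector,
    average_features,
    basic_features,
    extract_features,
    morphology_moments,
    smoothness,
    symmetry_coefficient,
)
from reachkin.segmentation import SubmovementWindow
from reachkin.signals import KinematicTrace

from conftest import closed_form_pulse


def beta_skewness(a: float, b: float) -> float:
    return 2 * (b - a) * np.sqrt(a + b + 1) / ((a + b + 2) * np.sqrt(a * b))


def beta_kurtosis(a: float, b: float) -> float:
    num = 6 * ((a - b) ** 2 * (a + b + 1) - a * b * (a + b + 2))
    return 3 + num / (a * b * (a + b + 2) * (a + b + 3))


class TestBasicFeatures:
    def test_minjerk_closed_forms(self, minjerk_pulse):
        trace, w = minjerk_pulse
        f = basic_features(trace, w)
        assert f["amplitude"] == pytest.approx(29.0, abs=0.1)
        assert f["duration"] == pytest.approx(1.50, abs=0.05)
        assert f["v_mean"] == pytest.approx(29.0 / 1.5, abs=0.2)
        assert f["v_max"] == pytest.approx(1.875 * 29.0 / 1.5, abs=0.4)
        assert f["a_max"] == pytest.approx(10 / np.sqrt(3) * 29.0 / 1.5**2, abs=1.5)

    def test_vmean_times_duration_equals_amplitude_exactly(self, minjerk_pulse):
        trace, w = minjerk_pulse
        f = basic_features(trace, w)
        assert f["v_mean"] * f["duration"] == pytest.approx(f["amplitude"], rel=1e-12)

    def test_negative_direction_reports_positive_magnitudes(self):
        trace, w = closed_form_pulse(A=-29.0)
        f = basic_features(trace, w)
        assert all(f[k] > 0 for k in ("amplitude", "v_max", "a_max", "jerk_max"))

    def test_static_window_rejected(self):
        t = np.arange(0, 2, 1e-3)
        z = np.zeros_like(t)
        trace = KinematicTrace("horizontal", 1000.0, t, 30 + z, z, z, z)
        w = SubmovementWindow("horizontal", 1, 100, 500, 900, 0.1, 0.5, 0.9, 1)
        with pytest.raises(ValidationError):
            basic_features(trace, w)


class TestSymmetry:
    def test_minjerk_is_symmetric(self, minjerk_pulse):
        trace, w = minjerk_pulse
        assert symmetry_coefficient(trace, w) == pytest.approx(1.00, abs=0.02)

    def test_beta_2_4_decelerates_longer(self):
        trace, w = closed_form_pulse(shape=(2.0, 4.0))
        # velocity mode at tau = 1/4: deceleration takes three times as long
        assert symmetry_coefficient(trace, w) == pytest.approx(3.0, rel=0.02)

    @given(a=st.floats(1.5, 4.0), b=st.floats(1.5, 4.0))
    def test_time_reversal_gives_the_reciprocal(self, a, b):
        trace, w = closed_form_pulse(shape=(a, b))
        rev = KinematicTrace(
            trace.channel, trace.fs, trace.t,
            trace.x[::-1].copy(), trace.v[::-1].copy(),
            trace.a[::-1].copy(), trace.j[::-1].copy(),
        )
        n = len(trace.t) - 1
        w_rev = SubmovementWindow(
            w.channel, w.phase_id,
            n - w.offset_i, n - w.peak_i, n - w.onset_i,
            trace.t[n - w.offset_i], trace.t[n - w.peak_i], trace.t[n - w.onset_i],
            -w.direction,
        )
        prod = symmetry_coefficient(trace, w) * symmetry_coefficient(rev, w_rev)
        assert prod == pytest.approx(1.0, rel=0.02)


class TestMorphologyMoments:
    def test_position_mean_against_integration_oracle(self, minjerk_pulse):
        trace, w = minjerk_pulse
        m = morphology_moments(trace, w)
        # brute-force oracle: mean of x over the window by dense quadrature
        tau = np.linspace(0, 1, 200001)
        oracle = 90.0 + 29.0 * np.trapezoid(beta_dist.cdf(tau, 3, 3), tau)
        assert oracle == pytest.approx(104.5, abs=1e-6)  # symmetry: x0 + A/2
        assert m["p_mean"] == pytest.approx(oracle, abs=1.0)

    def test_p_root_mean_against_integration_oracle(self, minjerk_pulse):
        trace, w = minjerk_pulse
        m = morphology_moments(trace, w)
        tau = np.linspace(0, 1, 200001)
        x = 90.0 + 29.0 * beta_dist.cdf(tau, 3, 3)
        assert m["p_root_mean"] == pytest.approx(np.trapezoid(x**2, tau), rel=0.005)
        assert m["variance"] == pytest.approx(
            np.trapezoid(x**2, tau) - np.trapezoid(x, tau) ** 2, rel=0.02
        )

    def test_minjerk_shape_moments_match_beta_3_3(self, minjerk_pulse):
        trace, w = minjerk_pulse
        m = morphology_moments(trace, w)
        assert m["skewness"] == pytest.approx(0.00, abs=0.02)
        assert m["kurtosis"] == pytest.approx(7.0 / 3.0, abs=0.02)

    @pytest.mark.parametrize("shape", [(2.0, 4.0), (2.5, 4.5), (4.0, 2.0)])
    def test_asymmetric_profiles_match_closed_form_beta_moments(self, shape):
        trace, w = closed_form_pulse(shape=shape)
        m = morphology_moments(trace, w)
        assert m["skewness"] == pytest.approx(beta_skewness(*shape), abs=0.02)
        assert m["kurtosis"] == pytest.approx(beta_kurtosis(*shape), abs=0.02)

    def test_beta_2_4_skewness_value(self):
        trace, w = closed_form_pulse(shape=(2.0, 4.0))
        assert morphology_moments(trace, w)["skewness"] == pytest.approx(0.468, abs=0.02)

    @given(scale=st.floats(0.2, 5.0), shift=st.floats(-3, 3))
    def test_shape_moments_invariant_to_amplitude_and_time_shift(self, scale, shift):
        trace, w = closed_form_pulse(shape=(2.5, 4.5))
        m0 = morphology_moments(trace, w)
        mod = KinematicTrace(
            trace.channel, trace.fs, trace.t + shift,
            trace.x * scale, trace.v * scale, trace.a * scale, trace.j * scale,
        )
        m1 = morphology_moments(mod, w)
        assert m1["skewness"] == pytest.approx(m0["skewness"], abs=1e-9)
        assert m1["kurtosis"] == pytest.approx(m0["kurtosis"], abs=1e-9)

    def test_static_window_rejected(self):
        t = np.arange(0, 2, 1e-3)
        z = np.zeros_like(t)
        trace = KinematicTrace("horizontal", 1000.0, t, 30 + z, z, z, z)
        w = SubmovementWindow("horizontal", 1, 100, 500, 900, 0.1, 0.5, 0.9, 1)
        with pytest.raises(ValidationError):
            morphology_moments(trace, w)


class TestSmoothness:
    def test_jerk_integral_is_four_amax_for_minjerk(self, minjerk_pulse):
        trace, w = minjerk_pulse
        a_max = basic_features(trace, w)["a_max"]
        assert smoothness(trace, w) == pytest.approx(4 * a_max, rel=0.02)

    def test_dimensionless_variant_attains_the_quintic_jerk_cost(self, minjerk_pulse):
        # exact cost of the quintic: integral of (60 - 360 tau + 360 tau^2)^2
        # over [0, 1] is 720, so the normalised jerk is sqrt(720)
        trace, w = minjerk_pulse
        cfg = FeatureConfig(smoothness_metric="dimensionless")
        assert smoothness(trace, w, cfg) == pytest.approx(np.sqrt(720), rel=0.005)

    def test_tremor_ripple_raises_roughness(self, minjerk_pulse):
        trace, w = minjerk_pulse
        ripple = 0.5 * np.sin(2 * np.pi * 5 * trace.t)
        from reachkin.signals import differentiate

        x = trace.x + ripple
        v = differentiate(trace.t, x)
        a = differentiate(trace.t, v)
        j = differentiate(trace.t, a)
        noisy = KinematicTrace(trace.channel, trace.fs, trace.t, x, v, a, j)
        assert smoothness(noisy, w) > smoothness(trace, w)

    def test_minjerk_minimises_jerk_among_two_pulse_composites(self):
        # split the same (A, T) into two sequential min-jerk subpulses:
        # every split is rougher than the single pulse
        from reachkin.signals import differentiate

        A, T, fs = 29.0, 1.5, 1000.0
        single, w = closed_form_pulse(A=A, T=T)
        base = smoothness(single, w)
        rng = np.random.default_rng(11)
        for _ in range(10):
            f_a, f_t = rng.uniform(0.2, 0.8), rng.uniform(0.2, 0.8)
            t = single.t
            x = np.full_like(t, 90.0)
            for (amp, start, dur) in [
                (f_a * A, 1.0, f_t * T),
                ((1 - f_a) * A, 1.0 + f_t * T, (1 - f_t) * T),
            ]:
                tau = np.clip((t - start) / dur, 0, 1)
                x = x + amp * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
            v = differentiate(t, x)
            a = differentiate(t, v)
            j = differentiate(t, a)
            comp = KinematicTrace("horizontal", fs, t, x, v, a, j)
            assert smoothness(comp, w) > base


class TestExtractAndAverage:
    def test_extract_returns_all_13_parameters(self, minjerk_pulse):
        trace, w = minjerk_pulse
        fv = extract_features(trace, w)
        assert set(fv.to_dict()) == set(PARAMETERS)
        assert all(np.isfinite(v) for v in fv.to_dict().values())

    def test_average_of_1_to_8_is_4_5(self):
        vecs = [FeatureVector(**{p: float(i) for p in PARAMETERS}) for i in range(1, 9)]
        avg, missing = average_features(vecs)
        assert not missing
        assert all(getattr(avg, p) == pytest.approx(4.5) for p in PARAMETERS)

    def test_average_of_constant_is_that_constant(self):
        vecs = [FeatureVector(**{p: 7.25 for p in PARAMETERS})] * 8
        avg, _ = average_features(vecs)
        assert getattr(avg, "v_max") == pytest.approx(7.25)

    def test_seven_phases_allowed_with_flag(self):
        vecs = [FeatureVector(**{p: float(i) for p in PARAMETERS}) for i in range(1, 8)]
        avg, missing = average_features(vecs)
        assert missing
        assert avg.duration == pytest.approx(4.0)

    def test_below_min_phases_rejected(self):
        vecs = [FeatureVector(**{p: 1.0 for p in PARAMETERS})] * 5
        with pytest.raises(ValidationError):
            average_features(vecs)


class TestGenerativeRecovery:
    def test_parameters_recovered_across_random_draws(self):
        """Amplitude, duration, v_max, symmetry and skewness extracted from
        random closed-form pulses match their generative values."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            A = rng.uniform(15, 45)
            T = rng.uniform(0.8, 3.5)
            a, b = rng.uniform(1.8, 4.5, size=2)
            trace, w = closed_form_pulse(A=A, T=T, shape=(a, b))
            fv = extract_features(trace, w)
            assert fv.amplitude == pytest.approx(A, rel=0.01)
            assert fv.duration == pytest.approx(T, rel=0.01)
            mode = (a - 1) / (a + b - 2)
            v_peak = A / T * beta_dist.pdf(mode, a, b)
            assert fv.v_max == pytest.approx(v_peak, rel=0.02)
            assert fv.symmetry == pytest.approx((1 - mode) / mode, rel=0.03)
            assert fv.skewness == pytest.approx(beta_skewness(a, b), abs=0.03)
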