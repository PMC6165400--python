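"""Calibration and feature extraction: analytic identities and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from enosecp import (
    FeatureConfig,
    SensorRecord,
    SimulationConfig,
    build_feature_matrix,
    default_smoothing_factors,
    ema_features,
    ema_filter,
    extract_features,
    integral_feature,
    make_class_profiles,
    max_feature,
    simulate_sample,
    subtract_baseline,
)


def _record(values, sr=10.0, injection_index=20, label=1):
    return SensorRecord(
        values=np.atleast_2d(values),
        sampling_rate=sr,
        injection_index=injection_index,
        label=label,
    )


class TestSubtractBaseline:
    def test_constant_trace_calibrates_to_zero(self):
        rec = _record(np.full(100, 2.0))
        cal = subtract_baseline(rec)
        np.testing.assert_allclose(cal.values, 0.0, atol=0)

    def test_step_trace(self):
        v = np.concatenate([np.full(20, 0.5), np.full(80, 2.0)])
        cal = subtract_baseline(_record(v))
        np.testing.assert_allclose(cal.values[0, :20], 0.0, atol=0)
        np.testing.assert_allclose(cal.values[0, 20:], 1.5, atol=0)

    def test_random_trace_has_zero_baseline_mean(self, rng):
        rec = _record(rng.normal(size=(3, 100)))
        cal = subtract_baseline(rec)
        np.testing.assert_allclose(
            cal.values[:, :20].mean(axis=1), 0.0, atol=1e-12
        )

    def test_idempotent(self, rng):
        rec = _record(rng.normal(size=100))
        once = subtract_baseline(rec)
        twice = subtract_baseline(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_window_past_injection_rejected(self):
        rec = _record(np.zeros(100))
        with pytest.raises(ValueError):
            subtract_baseline(rec, FeatureConfig(baseline_window=(0.0, 5.0)))


class TestMaxFeature:
    @pytest.mark.parametrize(
        "signal,expected",
        [([0.0, 1.5, -2.0, 0.3], 2.0), ([0.0, 0.0], 0.0), ([-3.5], 3.5)],
    )
    def test_definition(self, signal, expected):
        assert max_feature(signal) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            max_feature([])

    def test_noiseless_rise_bounded_by_amplitude(self):
        """First-order rise of amplitude A: Vmax in [A(1-e^-T/tau), A]."""
        prof = make_class_profiles(2, 1, 0.0, seed=3, timescale=0.1)
        cfg = SimulationConfig(noise_sd=0.0, drift_slope_sd=0.0, amplitude_jitter_sd=0.0)
        rec = simulate_sample(prof, 1, cfg, seed=0)
        cal = subtract_baseline(rec)
        amp = prof.amplitudes[0, 0]
        tau = prof.rise_tau[0]
        vmax = max_feature(cal.values[0])
        assert amp * (1 - np.exp(-cfg.rise_duration / tau)) - 1e-9 <= vmax <= amp + 1e-9


class TestIntegralFeature:
    def test_constant_signal_integrates_to_c_times_T(self):
        # inclusive-endpoint grid: 101 samples at 10 Hz span exactly 10 s
        v = np.full(101, 3.0)
        assert integral_feature(v, 10.0) == pytest.approx(30.0, abs=1e-9)

    def test_zero_signal(self):
        assert integral_feature(np.zeros(50), 10.0) == 0.0

    def test_linear_ramp_trapezoid_exact(self):
        t = np.arange(101) / 10.0  # [0, 10] inclusive
        assert integral_feature(t, 10.0) == pytest.approx(50.0, abs=1e-6)

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            integral_feature(np.zeros(50), 10.0, window=(0.0, 100.0))


class TestEmaFeatures:
    def test_a_equal_1_is_first_difference(self, rng):
        v = rng.normal(size=200)
        y = ema_filter(v, 1.0)
        np.testing.assert_allclose(y[1:], np.diff(v), atol=1e-12)
        assert y[0] == v[0]

    def test_ramp_at_a1_gives_constant_step(self):
        m = 0.25
        v = m * np.arange(1, 101)  # V(1)=m so y(1)=m too
        assert ema_features(v, 1.0) == (pytest.approx(m), pytest.approx(m))

    def test_zero_signal(self):
        assert ema_features(np.zeros(50), 0.1) == (0.0, 0.0)

    def test_default_smoothing_factors_at_full_rate(self):
        assert default_smoothing_factors(100.0) == (1e-4, 1e-3, 1e-2)

    @pytest.mark.parametrize("a", [0.0, -0.1, 1.5])
    def test_invalid_smoothing_factor_rejected(self, a):
        with pytest.raises(ValueError):
            ema_filter(np.zeros(10), a)

    def test_window_restriction(self):
        v = np.concatenate([np.zeros(50), np.full(50, 10.0)])
        mn_full, mx_full = ema_features(v, 1.0)
        mn_late, mx_late = ema_features(v, 1.0, window=(60, 101))
        assert mx_full == 10.0  # the jump at k=51
        assert mx_late == 0.0  # constant after the jump

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        a=st.floats(min_value=1e-4, max_value=1.0),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_matches_bruteforce_recurrence(self, a, seed):
        v = np.random.default_rng(seed).normal(size=100)
        np.testing.assert_allclose(
            ema_filter(v, a), oracles.naive_ema(v, a), rtol=1e-10, atol=1e-12
        )


class TestLinearity:
    """Features respond to scalar multiples of V as their formulas dictate."""

    @pytest.mark.parametrize("scale", [2.5, -3.0])
    def test_scaling(self, rng, scale):
        v = rng.normal(size=100)
        assert max_feature(scale * v) == pytest.approx(abs(scale) * max_feature(v))
        assert integral_feature(scale * v, 10.0) == pytest.approx(
            scale * integral_feature(v, 10.0)
        )
        mn, mx = ema_features(v, 0.05)
        smn, smx = ema_features(scale * v, 0.05)
        expect = sorted((scale * mn, scale * mx))
        assert (smn, smx) == (pytest.approx(expect[0]), pytest.approx(expect[1]))


class TestExtractFeatures:
    def test_16_sensors_give_128_features(self, rng):
        rec = _record(rng.normal(size=(16, 340)))
        vec, names = extract_features(rec)
        assert vec.shape == (128,)
        assert len(names) == 128
        assert len(set(names)) == 128

    def test_single_sensor_gives_8(self, rng):
        vec, names = extract_features(_record(rng.normal(size=(1, 340))))
        assert vec.shape == (8,)
        assert names[0] == "s01_max" and names[1] == "s01_int"

    def test_constant_record_gives_zero_vector(self):
        vec, _ = extract_features(_record(np.full((3, 340), 1.7)))
        np.testing.assert_allclose(vec, 0.0, atol=1e-12)


class TestBuildFeatureMatrix:
    def test_small_matrix_shape(self, rng):
        recs = [_record(rng.normal(size=(2, 100)), label=i + 1) for i in range(2)]
        fm = build_feature_matrix(recs)
        assert fm.values.shape == (2, 16)
        np.testing.assert_array_equal(fm.labels, [1, 2])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_feature_matrix([])

    def test_heterogeneous_records_rejected(self, rng):
        recs = [
            _record(rng.normal(size=(2, 100))),
            _record(rng.normal(size=(3, 100))),
        ]
        with pytest.raises(ValueError):
            build_feature_matrix(recs)

    def test_accepts_generator_input(self, rng):
        fm = build_feature_matrix(
            _record(rng.normal(size=(2, 100)), label=i) for i in (1, 2, 1)
        )
        assert fm.n_samples == 3
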