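import numpy as np
import pytest

from calscreen.synthetic import PulseShapeParams, WellModel, _render, simulate_well
from calscreen.waveform import (
    DetectorConfig,
    PulseEvent,
    Trace,
    compute_features,
    detect_pulses,
    differentiate,
    estimate_background,
    smooth,
)


def make_trace(values, rate_hz=2.0, well="B2", window="baseline"):
    values = np.asarray(values, dtype=float)
    times = np.arange(values.size) / rate_hz
    return Trace(well, times, values, rate_hz, window)


def kernel_trace(onsets, amplitudes, baseline=1000.0, rate_hz=2.0, duration=200.0,
                 drift=0.0, noise_sd=0.0, seed=0, **shape_kwargs):
    shape = PulseShapeParams(**shape_kwargs) if shape_kwargs else PulseShapeParams()
    times = np.arange(int(duration * rate_hz)) / rate_hz
    values = baseline + drift * times + _render(
        times, np.asarray(onsets, float), np.asarray(amplitudes, float), shape
    )
    if noise_sd:
        values = values + np.random.default_rng(seed).normal(0, noise_sd, times.size)
    return Trace("B2", times, values, rate_hz, "baseline")


class TestTrace:
    def test_rejects_non_uniform_times(self):
        times = np.array([0.0, 0.5, 1.01, 1.5])
        with pytest.raises(ValueError, match="non-uniform"):
            Trace("B2", times, np.zeros(4), 2.0)

    def test_rejects_short_trace(self):
        with pytest.raises(ValueError):
            Trace("B2", np.array([0.0]), np.array([1.0]), 2.0)

    def test_rejects_bad_rate(self):
        with pytest.raises(ValueError):
            Trace("B2", np.arange(4) / 4.0, np.zeros(4), 4.0)


class TestSmooth:
    def test_constant_is_fixed_point(self):
        trace = make_trace(np.full(100, 7.25))
        assert np.allclose(smooth(trace, 2.5).values, 7.25, atol=1e-12)

    def test_mean_preserved(self):
        rng = np.random.default_rng(0)
        trace = make_trace(1000 + rng.normal(0, 50, 400))
        out = smooth(trace, 2.5)
        assert np.mean(out.values) == pytest.approx(np.mean(trace.values), rel=1e-9)

    def test_spike_becomes_plateau(self):
        values = np.zeros(51)
        values[25] = 10.0  # interior spike, window of 5 samples -> h/w plateau
        out = smooth(make_trace(values), 2.5).values
        assert np.allclose(out[23:28], 2.0, atol=1e-12)
        assert np.allclose(out[:22], 0.0) and np.allclose(out[29:], 0.0)

    def test_linear_ramp_preserved_on_interior(self):
        trace = make_trace(5.0 + 3.0 * np.arange(100) / 2.0)
        out = smooth(trace, 2.5).values
        assert np.allclose(out[2:-2], trace.values[2:-2], atol=1e-9)

    def test_window_below_two_samples_rejected(self):
        with pytest.raises(ValueError, match="window"):
            smooth(make_trace(np.zeros(50)), 0.5)


class TestDifferentiate:
    def test_constant_gives_zeros(self):
        assert np.allclose(differentiate(make_trace(np.full(50, 3.0))), 0.0)

    def test_ramp_slope_exact(self):
        trace = make_trace(3.0 * np.arange(80) / 2.0)  # 3 RLU/s
        assert np.allclose(differentiate(trace), 3.0, atol=1e-9)

    def test_sine_derivative_amplitude(self):
        rate, freq, amp = 10.0, 0.05, 20.0
        times = np.arange(2000) / rate
        trace = Trace("B2", times, amp * np.sin(2 * np.pi * freq * times), rate)
        omega = 2 * np.pi * freq
        assert np.max(np.abs(differentiate(trace))) == pytest.approx(omega * amp, rel=0.01)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            differentiate(make_trace(np.zeros(2)))


class TestDetectPulses:
    def test_flat_noisy_trace_yields_no_large_pulses(self):
        rng = np.random.default_rng(7)
        trace = make_trace(1000 + rng.normal(0, 10, 2400))
        events = detect_pulses(trace)
        assert sum(ev.is_large for ev in events) == 0

    def test_recovers_ground_truth_events(self):
        # 12 injected events, per-pulse amplitude/noise ratio >= 10, fixed seed
        model = WellModel(base_rate=6.0, noise_sd=10.0)
        shape = PulseShapeParams(amplitude_mean=120.0, amplitude_cv=0.05,
                                 decay_time_constant=4.0)
        trace, truth = simulate_well(model, shape, seed=3)
        assert truth.n_events == 12
        events = [ev for ev in detect_pulses(trace) if ev.is_large]
        assert len(events) == 12
        for event, true_peak in zip(events, truth.peak_times):
            assert abs(event.top_time - true_peak) <= 1.0

    def test_pulse_pair_separation_vs_refractory(self):
        cfg = DetectorConfig(smooth_window=1.0)
        two = kernel_trace([50.0, 53.0], [100.0, 100.0], decay_time_constant=1.0)
        assert len(detect_pulses(two, cfg)) == 2
        merged = kernel_trace([50.0, 51.0], [100.0, 100.0], decay_time_constant=1.0)
        assert len(detect_pulses(merged, cfg)) == 1

    def test_events_sorted_and_non_overlapping(self):
        model = WellModel(base_rate=20.0, noise_sd=10.0)
        shape = PulseShapeParams(amplitude_mean=120.0, amplitude_cv=0.05)
        trace, _ = simulate_well(model, shape, seed=11)
        events = detect_pulses(trace)
        for prev, nxt in zip(events, events[1:]):
            assert prev.top_time < nxt.top_time
            assert prev.end_time <= nxt.bottom_time + 1e-9

    def test_threshold_monotonicity(self):
        shape = PulseShapeParams(amplitude_mean=120.0, amplitude_cv=0.05)
        for seed in range(3):
            trace, _ = simulate_well(WellModel(base_rate=15.0, noise_sd=10.0), shape, seed=seed)
            counts = [
                len(detect_pulses(trace, DetectorConfig(derivative_threshold_k=k)))
                for k in (2.0, 3.0, 5.0, 8.0, 12.0)
            ]
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_scale_equivariance(self):
        shape = PulseShapeParams(amplitude_mean=120.0, amplitude_cv=0.05)
        trace, _ = simulate_well(WellModel(base_rate=12.0, noise_sd=10.0), shape, seed=4)
        c = 3.7
        scaled = Trace(trace.well_id, trace.times, trace.values * c, trace.rate_hz)
        f1 = compute_features(trace, detect_pulses(trace))
        f2 = compute_features(scaled, detect_pulses(scaled))
        assert f2.peak_number == f1.peak_number
        assert f2.mean_width == f1.mean_width
        assert f2.mean_peak_to_peak == f1.mean_peak_to_peak
        assert f2.mean_amplitude == pytest.approx(c * f1.mean_amplitude, rel=1e-9)
        assert f2.mean_auc == pytest.approx(c * f1.mean_auc, rel=1e-9)

    def test_sampling_rate_robustness(self):
        rng = np.random.default_rng(9)
        onsets = np.sort(rng.uniform(5, 1190, 18))
        onsets = onsets[np.concatenate([[True], np.diff(onsets) > 8])]
        amps = np.full(onsets.size, 100.0)
        numbers = []
        for rate in (2.0, 10.0):
            trace = kernel_trace(onsets, amps, rate_hz=rate, duration=1200.0)
            feats = compute_features(trace, detect_pulses(trace))
            numbers.append(feats.peak_number)
            assert feats.n_events_large == onsets.size
        assert numbers[0] == numbers[1]


class TestEstimateBackground:
    def test_no_events_returns_smoothed_trace(self):
        rng = np.random.default_rng(1)
        trace = make_trace(1000 + rng.normal(0, 5, 400))
        assert np.array_equal(estimate_background(trace, []), smooth(trace, 2.5).values)

    def test_constant_baseline_recovered(self):
        noise_sd = 5.0
        trace = kernel_trace([40.0, 90.0, 150.0], [100.0] * 3, baseline=1000.0,
                             noise_sd=noise_sd, seed=2)
        events = detect_pulses(trace)
        background = estimate_background(trace, events)
        assert np.max(np.abs(background - 1000.0)) < 3 * noise_sd

    def test_linear_drift_recovered(self):
        noise_sd = 5.0
        a, b = 1000.0, -0.1
        trace = kernel_trace([40.0, 90.0, 150.0], [100.0] * 3, baseline=a, drift=b,
                             noise_sd=noise_sd, seed=3)
        events = detect_pulses(trace)
        background = estimate_background(trace, events)
        assert np.max(np.abs(background - (a + b * trace.times))) < 3 * noise_sd

    def test_full_coverage_rejected(self):
        trace = make_trace(np.linspace(0, 100, 50))
        event = PulseEvent(0.0, 1.0, 24.5, 10.0, 1000.0, 1000.0, 5.0, True)
        with pytest.raises(ValueError, match="background"):
            estimate_background(trace, [event])


class TestComputeFeatures:
    @staticmethod
    def _event(top_time, amplitude=50.0, large=True):
        return PulseEvent(
            bottom_time=top_time - 2.0, top_time=top_time, end_time=top_time + 10.0,
            amplitude=amplitude, width_rise=2000.0, width_return=10000.0,
            auc=amplitude * 5.0, is_large=large,
        )

    def test_peak_number_normalization(self):
        trace = make_trace(np.zeros(2400))  # 1200 s at 2 Hz
        events = [self._event(50.0 + 90.0 * i) for i in range(12)]
        feats = compute_features(trace, events)
        assert feats.peak_number == pytest.approx(6.0)

    def test_peak_to_peak(self):
        trace = make_trace(np.zeros(2400))
        events = [self._event(100.0), self._event(160.0)]
        feats = compute_features(trace, events)
        assert feats.mean_peak_to_peak == pytest.approx(60000.0)

    def test_small_events_not_counted(self):
        trace = make_trace(np.zeros(2400))
        events = [self._event(100.0), self._event(200.0, amplitude=2.0, large=False)]
        feats = compute_features(trace, events)
        assert feats.n_events_raw == 2
        assert feats.n_events_large == 1
        assert feats.peak_number == pytest.approx(0.5)

    def test_degenerate_well_reports_absent_features(self):
        trace = make_trace(np.zeros(2400))
        feats = compute_features(trace, [])
        assert feats.peak_number == 0.0
        assert feats.mean_width is None
        assert feats.mean_amplitude is None
        assert feats.mean_auc is None
        assert feats.mean_peak_to_peak is None

    def test_kernel_closed_form_amplitude_and_auc(self):
        amp, rise, tau = 100.0, 2.0, 8.0
        cfg = DetectorConfig(return_fraction=0.95)
        trace = kernel_trace([50.0], [amp], rise_time=rise, decay_time_constant=tau)
        feats = compute_features(trace, detect_pulses(trace, cfg), cfg)
        assert feats.n_events_large == 1
        assert feats.mean_amplitude == pytest.approx(amp, rel=0.05)
        closed_form = amp * (rise / 2.0 + cfg.return_fraction * tau)
        assert feats.mean_auc == pytest.approx(closed_form, rel=0.10)

    def test_width_mode_switch(self):
        trace = kernel_trace([50.0], [100.0])
        events = detect_pulses(trace)
        by_return = compute_features(trace, events, DetectorConfig(width_mode="return"))
        by_rise = compute_features(trace, events, DetectorConfig(width_mode="rise"))
        assert by_return.mean_width == events[0].width_return
        assert by_rise.mean_width == events[0].width_rise
        assert by_rise.mean_width < by_return.mean_width
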