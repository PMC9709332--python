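import numpy as np
import pytest

from lnsynapse import (
    RecoveryFit,
    Trace,
    TuningCurve,
    adaptation_properties,
    fit_recovery,
    peak_response_cbc,
    peak_response_cone,
    ppd_command_trace,
    run_ppd,
    square_wave_stimulus,
    tuning_curve,
    tuning_range,
)
from lnsynapse.protocols import ProtocolError, peak_to_base_ratio


class TestSquareWave:
    def test_one_hz_half_cycles(self):
        stim = square_wave_stimulus(1.0)
        x = stim.values
        assert x[:500].sum() == 500  # 500 ms light
        assert x[500:1000].sum() == 0  # 500 ms dark
        assert len(stim) == 8000  # 8 periods

    def test_four_hz_half_cycles(self):
        stim = square_wave_stimulus(4.0)
        x = stim.values
        assert np.all(x[:125] == 1.0) and np.all(x[125:250] == 0.0)
        assert len(stim) == 4000

    @pytest.mark.parametrize("freq", [1.0, 3.0, 16.0, 333.0])
    def test_duty_cycle_is_half(self, freq):
        stim = square_wave_stimulus(freq)
        assert stim.values.mean() == pytest.approx(0.5, abs=1e-3)

    def test_out_of_range_warns_not_errors(self):
        with pytest.warns(UserWarning):
            square_wave_stimulus(500.0, 1000)

    def test_non_integer_period_preserves_duration(self):
        stim = square_wave_stimulus(333.0)
        assert abs(len(stim) - 4000) <= 2

    def test_no_slow_duty_modulation(self):
        # quantisation must not alias into a low-frequency duty beat
        x = square_wave_stimulus(333.0).values
        local = np.convolve(x, np.ones(40) / 40, "valid")
        assert local.min() > 0.4 and local.max() < 0.6


class TestPeakExtraction:
    def test_flat_trace_zero_peak(self):
        out = Trace(values=np.zeros(2000), kind="voltage_mV")
        assert peak_response_cbc(out, 1000.0) == 0.0

    def test_triangular_bump_height(self):
        v = np.zeros(2000)
        v[1500:1600] = np.concatenate([np.linspace(0, 2.5, 50), np.linspace(2.5, 0, 50)])
        out = Trace(values=v, kind="voltage_mV")
        assert peak_response_cbc(out, 1000.0) == pytest.approx(2.5)

    def test_only_last_period_counts(self):
        v = np.zeros(2000)
        v[200] = 9.0  # big bump in the first period
        v[1700] = 1.0  # smaller bump in the last
        out = Trace(values=v, kind="voltage_mV")
        assert peak_response_cbc(out, 1000.0) == 1.0

    def test_short_trace_rejected(self):
        out = Trace(values=np.zeros(10), kind="voltage_mV")
        with pytest.raises(ProtocolError):
            peak_response_cbc(out, 100.0)

    def test_cone_peak_gap_definition(self):
        v = np.full(1500, 1.0)
        v[-300] = 3.5
        out = Trace(values=v, kind="fluorescence")
        assert peak_response_cone(out, 1.0) == pytest.approx(2.5)

    def test_cone_gap_may_be_negative(self):
        out = Trace(values=np.full(1200, 0.4), kind="fluorescence")
        assert peak_response_cone(out, 1.0) == pytest.approx(-0.6)

    def test_cone_needs_a_full_second(self):
        with pytest.raises(ProtocolError):
            peak_response_cone(Trace(values=np.zeros(500), kind="fluorescence"), 0.0)


class TestTuningCurveAndRange:
    def test_frequencies_sorted_regardless_of_input_order(self, cbc_fast):
        c = tuning_curve(cbc_fast.model, (8.0, 1.0, 4.0))
        np.testing.assert_array_equal(c.frequencies, [1.0, 4.0, 8.0])

    def test_hand_traced_range_rule(self):
        curve = TuningCurve(
            frequencies=[1, 2, 4, 8, 16], peaks=[1.0, 1.0, 0.9, 0.5, 0.02]
        )
        rng = tuning_range(curve)
        assert rng.f_start == 2.0 and not rng.start_open
        assert rng.f_end == 16.0 and not rng.end_open

    def test_flat_curve_has_open_end(self):
        curve = TuningCurve(frequencies=[1, 2, 4], peaks=[1.0, 1.0, 1.0])
        rng = tuning_range(curve)
        assert rng.f_start == 4.0
        assert rng.f_end is None and rng.end_open

    def test_curve_collapsing_above_baseline(self):
        curve = TuningCurve(frequencies=[1, 2, 4], peaks=[1.0, 0.0, 0.0])
        rng = tuning_range(curve)
        assert rng.f_start == 1.0
        assert rng.f_end == 2.0

    def test_missing_baseline_rejected(self):
        with pytest.raises(ProtocolError):
            TuningCurve(frequencies=[2, 4], peaks=[1.0, 0.5])

    def test_csv_round_trip(self, tmp_path):
        curve = TuningCurve(frequencies=[1, 4, 8], peaks=[1.0, 0.4, 0.1])
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        back = TuningCurve.from_csv(path)
        np.testing.assert_allclose(back.peaks, curve.peaks)

    def test_slow_channel_tuned_below_fast(self, cbc_fast, cbc_slow):
        freqs = (1.0, 2.0, 4.0, 8.0, 16.0)
        fast = tuning_curve(cbc_fast.model, freqs)
        slow = tuning_curve(cbc_slow.model, freqs)
        assert np.all(slow.peaks[1:] <= fast.peaks[1:])

    def test_peak_to_base_ratio_requires_nonzero_plateau(self):
        out = Trace(values=np.zeros(1000), kind="voltage_mV")
        with pytest.raises(ProtocolError):
            peak_to_base_ratio(out, 1000.0)


class TestPPD:
    def test_command_trace_geometry(self):
        t = ppd_command_trace(10.0)
        v = t.values
        assert v.min() == -70.0 and v.max() == -30.0
        # pulse + 10-ms gap + pulse spans 30 ms, of which 20 ms at -30 mV
        pulse_region = np.where(v == -30.0)[0]
        assert pulse_region[-1] - pulse_region[0] + 1 == 30
        assert (v == -30.0).sum() == 20

    def test_twenty_second_interval_supported(self):
        t = ppd_command_trace(20000.0)
        assert len(t) == 100 + 10 + 20000 + 10 + 50

    def test_sub_dt_interval_rejected(self):
        with pytest.raises(ProtocolError):
            ppd_command_trace(0.5)

    def test_full_recovery_at_long_intervals(self, cbc_fast):
        res = run_ppd(cbc_fast.model, [10.0, 100.0, 1000.0, 20000.0])
        assert res.ratios[-1] == pytest.approx(1.0, abs=1e-3)

    def test_ratios_nondecreasing_in_interval(self, all_presets):
        intervals = np.geomspace(10, 20000, 8)
        for preset in all_presets.values():
            res = run_ppd(preset.model, intervals)
            assert np.all(np.diff(res.ratios) >= -1e-9)

    def test_fitted_tau_matches_analytic_recovery_constant(self, cbc_fast, cbc_slow):
        for preset in (cbc_fast, cbc_slow):
            res = run_ppd(preset.model)
            _, tau = adaptation_properties(-70.0, preset.model)
            assert res.fit.tau_ms == pytest.approx(tau, rel=0.15)


class TestRecoveryFit:
    def test_exact_parameters_recovered(self):
        dt = np.geomspace(10, 20000, 12)
        r = 0.6 * (1.0 - np.exp(-dt / 150.0)) + 0.4
        fit = fit_recovery(dt, r)
        assert fit.flu == pytest.approx(0.6, rel=1e-3)
        assert fit.base == pytest.approx(0.4, rel=1e-3)
        assert fit.tau_ms == pytest.approx(150.0, rel=1e-3)
        resid = 0.6 * (1 - np.exp(-dt / fit.tau_ms)) + fit.base - r
        assert np.max(np.abs(resid)) < 1e-6

    def test_constant_ratios_flagged_nonidentifiable(self):
        fit = fit_recovery([10, 100, 1000], [1.0, 1.0, 1.0])
        assert not fit.identifiable
        assert np.isnan(fit.tau_ms)

    def test_invariant_to_point_order(self):
        dt = np.array([500.0, 10.0, 5000.0, 100.0, 1000.0])
        r = 0.5 * (1.0 - np.exp(-dt / 300.0)) + 0.5
        a = fit_recovery(dt, r)
        b = fit_recovery(dt[::-1], r[::-1])
        assert a.tau_ms == pytest.approx(b.tau_ms, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ProtocolError):
            fit_recovery([10, 100], [0.5, 0.9])
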