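from dataclasses import replace

import numpy as np
import pytest

from lnsynapse import (
    FitSpec,
    LNModel,
    PhotoFilterParams,
    RABParams,
    SigmoidParams,
    Trace,
    cbc_feature_error,
    cone_trace_error,
    constraint_penalty,
    fit_model,
    gen_cbc_features,
    gen_cone_trace,
    square_wave_stimulus,
)
from lnsynapse.fitting import _normalise
from lnsynapse.synthetic_data import CBCFeatures, ConeTraceData, TuningCurve

TINY_SEARCH = dict(n_starts=1, maxiter=300, polish_maxiter=200, de_popsize=4, de_maxiter=5)


class TestCbcFeatureError:
    def test_model_matches_its_own_features(self, cbc_fast):
        ds = gen_cbc_features(cbc_fast, noise_sd=0.0)
        assert cbc_feature_error(cbc_fast.model, ds.payload) < 1e-9

    def test_l1_contract_on_single_peak(self, cbc_fast):
        ds = gen_cbc_features(cbc_fast, noise_sd=0.0)
        peaks = ds.payload.curve.peaks.copy()
        peaks[3] += 0.37
        perturbed = CBCFeatures(
            curve=TuningCurve(ds.payload.curve.frequencies, peaks),
            ratio_at_1hz=ds.payload.ratio_at_1hz,
        )
        assert cbc_feature_error(cbc_fast.model, perturbed) == pytest.approx(0.37, abs=1e-9)

    def test_error_decreases_toward_truth(self, cbc_fast):
        # walking one parameter back toward the generating value shrinks
        # the objective monotonically along the sampled path
        ds = gen_cbc_features(cbc_fast, noise_sd=0.0)
        true_k = cbc_fast.model.rab.k_s
        errs = []
        for factor in (2.0, 1.5, 1.2, 1.0):
            model = replace(
                cbc_fast.model, rab=replace(cbc_fast.model.rab, k_s=true_k * factor)
            )
            errs.append(cbc_feature_error(model, ds.payload))
        assert all(a > b for a, b in zip(errs, errs[1:]))

    def test_missing_baseline_frequency_rejected(self, cbc_fast):
        curve = TuningCurve(frequencies=[1.0, 2.0], peaks=[1.0, 0.5])
        bad = CBCFeatures(
            curve=TuningCurve(frequencies=[2.0, 4.0, 1.0], peaks=[1, 1, 1]),
            ratio_at_1hz=1.0,
        )
        bad.curve.frequencies = np.array([2.0, 4.0, 8.0])  # drop 1 Hz
        with pytest.raises(ValueError):
            cbc_feature_error(cbc_fast.model, bad)


class TestConeTraceError:
    def test_identical_traces_zero_error(self, all_presets):
        preset = all_presets["cone_az"]
        ds = gen_cone_trace(preset, square_wave_stimulus(2.0, 2000), noise_sd=0.0)
        # the target's rest is read off its first sample, which differs from
        # the exact resting output by the first millisecond of response
        assert cone_trace_error(preset.model, ds.payload) < 1e-4

    def test_scale_invariance(self, all_presets):
        preset = all_presets["cone_az"]
        ds = gen_cone_trace(preset, square_wave_stimulus(2.0, 2000), noise_sd=0.0)
        scaled = ConeTraceData(
            stimulus=ds.payload.stimulus,
            trace=ds.payload.trace.with_values(3.0 * ds.payload.trace.values),
        )
        assert cone_trace_error(preset.model, scaled) < 1e-4

    def test_normalised_l1_by_hand_on_toy_traces(self):
        a = np.array([1.0, 1.0, 3.0, 2.0, 1.0])  # rest 1, peak |2|
        b = np.array([2.0, 2.0, 2.0, 6.0, 2.0])  # rest 2, peak |4|
        an = _normalise(a, 1.0)  # [0, 0, 1, .5, 0]
        bn = _normalise(b, 2.0)  # [0, 0, 0, 1, 0]
        assert np.sum(np.abs(an - bn)) == pytest.approx(1.5)

    def test_constant_target_rejected(self, all_presets):
        preset = all_presets["cone_az"]
        stim = square_wave_stimulus(2.0, 2000)
        flat = ConeTraceData(
            stimulus=stim,
            trace=Trace(values=np.full(len(stim), 5.0), kind="fluorescence"),
        )
        with pytest.raises(ValueError):
            cone_trace_error(preset.model, flat)


class TestConstraintPenalty:
    def test_presets_are_feasible(self, all_presets):
        for preset in all_presets.values():
            assert constraint_penalty(preset.model) == 0.0

    def test_fast_kinetics_penalised(self, cbc_fast):
        # a large drive-independent rate floor pushes tau below 1 ms
        bad = replace(
            cbc_fast.model,
            rab=RABParams(A_s=0.0, B_s=1.0, C_s=0.5, k_s=1.0, n_s=1.0, N=1.0),
        )
        assert constraint_penalty(bad) > 0.0

    def test_continuous_at_the_boundary(self, cbc_fast):
        # penalty grows continuously from zero as C_s crosses the limit
        def penalty_at(c):
            model = replace(
                cbc_fast.model,
                rab=RABParams(A_s=0.0, B_s=1.0, C_s=c, k_s=1.0, n_s=1.0, N=1.0),
            )
            return constraint_penalty(model)

        # with k_s = n_s = 1 the fastest grid point is -75 mV (recovery
        # flux dominates), where tau ~ 0.050/C_s: boundary near C_s = 0.05
        cs = np.linspace(0.03, 0.07, 41)
        vals = np.array([penalty_at(c) for c in cs])
        assert vals[0] == 0.0 and vals[-1] > 0.0
        assert np.all(np.diff(vals) >= 0.0)
        assert np.max(np.diff(vals)) < 1e4 * 0.02  # no jump discontinuity

    def test_ln_filter_tau_floor(self):
        model = LNModel(
            filter=PhotoFilterParams(gamma=0.005),
            nl=SigmoidParams(m=1.0, half=0.0, slope=1.0),
        )
        assert constraint_penalty(model) > 0.0


class TestFitModel:
    def test_truth_template_is_a_fixed_point(self, cbc_fast):
        ds = gen_cbc_features(cbc_fast, noise_sd=0.0)
        spec = FitSpec(model=cbc_fast.model, objective="cbc_features", seed=0, **TINY_SEARCH)
        res = fit_model(spec, ds.payload)
        assert res.objective < 1e-6
        _, = (res.tau_r_70_ms,)
        assert res.tau_r_70_ms == pytest.approx(cbc_fast.tau_r_70_ms, rel=1e-3)

    def test_best_objective_not_worse_than_any_start(self, cbc_fast):
        ds = gen_cbc_features(cbc_fast, noise_sd=0.05)
        spec = FitSpec(model=cbc_fast.model, objective="cbc_features", seed=3, **TINY_SEARCH)
        res = fit_model(spec, ds.payload)
        assert all(res.objective <= rec["objective"] + 1e-12 for rec in res.starts)

    def test_deterministic_given_seed(self, cbc_fast):
        ds = gen_cbc_features(cbc_fast, noise_sd=0.05, seed=7)
        spec = FitSpec(model=cbc_fast.model, objective="cbc_features", seed=7, **TINY_SEARCH)
        a = fit_model(spec, ds.payload)
        b = fit_model(spec, ds.payload)
        assert a.objective == b.objective
        assert a.model == b.model

    def test_objective_invariant_to_frequency_order(self, cbc_fast):
        ds = gen_cbc_features(cbc_fast, noise_sd=0.03, seed=2)
        shuffled = CBCFeatures(
            curve=TuningCurve(
                ds.payload.curve.frequencies[::-1], ds.payload.curve.peaks[::-1]
            ),
            ratio_at_1hz=ds.payload.ratio_at_1hz,
        )
        assert cbc_feature_error(cbc_fast.model, shuffled) == pytest.approx(
            cbc_feature_error(cbc_fast.model, ds.payload), rel=1e-12
        )

    def test_cone_trace_fit_truth_template_fixed_point(self, all_presets):
        preset = all_presets["cone_az"]
        ds = gen_cone_trace(preset, square_wave_stimulus(2.0, 2000), noise_sd=0.0)
        spec = FitSpec(model=preset.model, objective="cone_trace", seed=0, **TINY_SEARCH)
        res = fit_model(spec, ds.payload)
        assert res.objective < 1e-3
        assert res.tau_r_70_ms == pytest.approx(preset.tau_r_70_ms, rel=0.01)

    def test_synapse_block_explains_depressing_data_better_than_ln(self, cbc_fast):
        # an LN model cannot reproduce features generated with synaptic
        # depression; its best objective stays far above the LNS one
        ds = gen_cbc_features(cbc_fast, noise_sd=0.0)
        lns_obj = cbc_feature_error(cbc_fast.model, ds.payload)
        ln_template = LNModel(
            filter=PhotoFilterParams(gamma=1.0),
            nl=SigmoidParams(m=10.0, half=0.5, slope=0.4),
        )
        spec = FitSpec(
            model=ln_template, objective="cbc_features", seed=1,
            n_starts=2, maxiter=300, polish_maxiter=200, de_popsize=4, de_maxiter=15,
        )
        ln_fit = fit_model(spec, ds.payload)
        assert lns_obj < 1e-9
        assert ln_fit.objective > 1.0

    def test_result_serialises(self, tmp_path, cbc_fast):
        ds = gen_cbc_features(cbc_fast, noise_sd=0.0)
        spec = FitSpec(model=cbc_fast.model, objective="cbc_features", seed=0, **TINY_SEARCH)
        res = fit_model(spec, ds.payload)
        res.to_json(tmp_path / "fit.json")
        import json

        payload = json.loads((tmp_path / "fit.json").read_text())
        assert payload["tau_r_70_ms"] == pytest.approx(res.tau_r_70_ms)
        assert len(payload["adaptation"]["v_mV"]) == 46
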