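"""Compartment-model evaluation, fitting, macro parameters and AIC."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from petkin.compartment import (
    MODEL_PRESETS,
    CompartmentFit,
    CompartmentParams,
    MacroParams,
    ModelConfig,
    TacModel,
    aic_score,
    fit_model,
    macro_params,
    model_tac,
    select_model,
)
from petkin.curves import SampledCurve
from petkin.input_function import InputFunction


def _ode_tissue(params, input_function, times):
    """Stiff numerical integration of the two-compartment system."""
    kt, kv = input_function.plasma_parent._knots()

    def rhs(t, y):
        cp = np.interp(t, kt, kv)
        return [params.K1 * cp - (params.k2 + params.k3) * y[0]
                + params.k4 * y[1],
                params.k3 * y[0] - params.k4 * y[1]]

    sol = solve_ivp(rhs, [0.0, times[-1]], [0.0, 0.0], t_eval=times,
                    method="LSODA", rtol=1e-10, atol=1e-13, max_step=0.25)
    return sol.y.sum(axis=0)


class TestModelTac:
    def test_matches_ode_oracle(self, observed_input, observed_model,
                                schedule):
        p = CompartmentParams(0.4, 0.3, 0.06, 0.03)
        mids = schedule.mids
        oracle = _ode_tissue(p, observed_input, mids)
        mine = observed_model.point_values(p, mids)
        assert np.max(np.abs(mine - oracle)) / oracle.max() < 1e-4

    def test_confluent_branch_matches_ode(self, observed_input,
                                          observed_model, schedule):
        # k3 = 0 with k2 = k4 makes the eigenvalues coincide exactly
        p = CompartmentParams(0.5, 0.3, 0.0, 0.3)
        mids = schedule.mids
        oracle = _ode_tissue(p, observed_input, mids)
        mine = observed_model.point_values(p, mids)
        assert np.max(np.abs(mine - oracle)) / oracle.max() < 1e-4

    def test_confluent_branch_continuous_in_k4(self, observed_model,
                                               schedule):
        base = observed_model.point_values(
            CompartmentParams(0.5, 0.3, 0.0, 0.3), schedule.mids)
        nearby = observed_model.point_values(
            CompartmentParams(0.5, 0.3, 0.0, 0.3 + 1e-7), schedule.mids)
        assert np.max(np.abs(base - nearby)) / base.max() < 1e-5

    def test_k3_zero_nested_in_one_tissue(self, observed_model):
        one = observed_model.frame_values(CompartmentParams(0.4, 0.3))
        two = observed_model.frame_values(
            CompartmentParams(0.4, 0.3, 0.0, 0.0))
        np.testing.assert_allclose(one, two, atol=1e-10)

    def test_k1_zero_leaves_only_blood_signal(self, observed_input,
                                              schedule):
        p = CompartmentParams(0.0, 0.3, vb=0.05)
        model = TacModel(observed_input, schedule)
        wb_only = 0.05 * np.array([
            observed_input.blood(t) for t in schedule.mids])
        np.testing.assert_allclose(
            model.point_values(p, schedule.mids), wb_only, atol=1e-12)

    def test_nonfinite_parameter_rejected(self):
        with pytest.raises(ValueError):
            CompartmentParams(np.nan, 0.3)

    def test_frame_average_vs_midpoint_close_on_late_frames(
            self, observed_input, schedule):
        p = CompartmentParams(0.4, 0.11, 0.036, 0.15, vb=0.036)
        avg = model_tac(p, observed_input, schedule)
        mid = model_tac(p, observed_input, schedule, frame_method="midpoint")
        assert np.allclose(avg[-3:], mid[-3:], rtol=0.05)
        # the late decay is convex, so the frame average sits above the
        # midpoint value
        assert np.all(avg[-3:] >= mid[-3:])


class TestMacroParams:
    def test_zero_k3_gives_zero_binding(self):
        m = macro_params(CompartmentParams(0.5, 0.25, 0.0, 0.1))
        assert (m.V_ND, m.BP_ND, m.V_T) == (2.0, 0.0, 2.0)

    def test_printed_formula_case(self):
        m = macro_params(CompartmentParams(0.3, 0.15, 0.05, 0.025))
        assert m.V_ND == pytest.approx(2.0)
        assert m.BP_ND == pytest.approx(2.0)
        assert m.V_T == pytest.approx(6.0)

    def test_undefined_bp_raises(self):
        p = dataclasses.replace(CompartmentParams(0.3, 0.15, 0.0, 0.0))
        object.__setattr__(p, "k3", 0.05)  # bypass constructor guard
        with pytest.raises(ValueError):
            macro_params(p)

    @given(st.floats(0.01, 5), st.floats(0.01, 5), st.floats(0, 5),
           st.floats(0.01, 5))
    def test_identity_holds_exactly(self, K1, k2, k3, k4):
        m = macro_params(CompartmentParams(K1, k2, k3, k4))
        assert m.V_T == m.V_ND * (1.0 + m.BP_ND)


class TestFitModel:
    def test_noise_free_recovery(self, observed_input, observed_model,
                                 schedule):
        truth = CompartmentParams(0.5, 0.4, 0.15, 0.05, vb=0.036)
        tac = observed_model.frame_values(truth)
        fit = fit_model(tac, observed_input, schedule, "2tcm_vb_fixed")
        assert fit.converged
        for name in ("K1", "k2", "k3", "k4"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(truth, name), rel=1e-3)

    def test_k3_zero_data_fit_by_two_tissue_gives_null_binding(
            self, observed_input, observed_model, schedule):
        tac = observed_model.frame_values(
            CompartmentParams(0.4, 0.15, vb=0.036))
        fit = fit_model(tac, observed_input, schedule, "2tcm_vb_fixed")
        assert fit.macro.BP_ND < 0.01

    def test_all_zero_tac_flagged_degenerate(self, observed_input, schedule):
        fit = fit_model(np.zeros(schedule.n_frames), observed_input,
                        schedule, "2tcm_vb_fixed")
        assert fit.params.K1 == 0.0
        assert any("degenerate" in w for w in fit.warnings)

    def test_rescaling_invariance(self, observed_input, observed_model,
                                  schedule):
        truth = CompartmentParams(0.4, 0.3, 0.06, 0.03, vb=0.036)
        tac = observed_model.frame_values(truth)
        fit = fit_model(tac, observed_input, schedule, "2tcm_vb_fixed")
        c = 7.3
        scaled_input = InputFunction(
            observed_input.plasma_parent.scaled(c),
            observed_input.whole_blood.scaled(c),
        )
        fit_scaled = fit_model(tac * c, scaled_input, schedule,
                               "2tcm_vb_fixed")
        assert fit_scaled.macro.V_T == pytest.approx(fit.macro.V_T, rel=1e-6)
        assert fit_scaled.macro.BP_ND == pytest.approx(fit.macro.BP_ND,
                                                       rel=1e-6)

    def test_free_vb_preset_recovers_blood_volume(self, observed_input,
                                                  observed_model, schedule):
        truth = CompartmentParams(0.4, 0.2, vb=0.07)
        tac = observed_model.frame_values(truth)
        fit = fit_model(tac, observed_input, schedule, "1tcm_vb_free")
        assert fit.params.vb == pytest.approx(0.07, rel=1e-2)

    def test_length_mismatch_rejected(self, observed_input, schedule):
        with pytest.raises(ValueError):
            fit_model(np.ones(5), observed_input, schedule, "2tcm_vb_fixed")


class TestModelSelection:
    def _fit(self, wrss, n_free, n=22, converged=True):
        cfgs = {2: "1tcm_vb_fixed", 3: "1tcm_vb_free", 4: "2tcm_vb_fixed",
                5: "2tcm_vb_free"}
        config = MODEL_PRESETS[cfgs[n_free]]
        p = CompartmentParams(0.4, 0.2, 0.05, 0.05, vb=0.036)
        return CompartmentFit(config, p, macro_params(p), wrss,
                              aic_score(wrss, n, n_free), n, converged,
                              np.zeros(n))

    def test_equal_wrss_prefers_fewer_parameters(self):
        best = select_model([self._fit(1.0, 4), self._fit(1.0, 3)])
        assert best.config.n_free == 3

    def test_lower_aic_wins(self):
        best = select_model([self._fit(1.0, 4), self._fit(10.0, 2)])
        assert best.config.n_free == 4

    def test_unconverged_fits_skipped_when_alternatives_exist(self):
        best = select_model([self._fit(0.1, 4, converged=False),
                             self._fit(1.0, 2)])
        assert best.config.n_free == 2

    def test_perfect_fit_gets_sentinel(self):
        assert aic_score(0.0, 22, 4) == float("-inf")

    def test_five_presets_exist(self):
        assert set(MODEL_PRESETS) == {
            "1tcm_vb_free", "1tcm_vb_fixed", "2tcm_vb_free",
            "2tcm_vb_fixed", "2tcm_vb_fixed_delay"}
        assert MODEL_PRESETS["2tcm_vb_fixed"].vb_value == pytest.approx(0.036)
        assert MODEL_PRESETS["2tcm_vb_fixed_delay"].fit_delay
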