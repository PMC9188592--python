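"""0D circuit elements and the multi-cycle integrator."""

import math
from dataclasses import replace

import numpy as np
import pytest

from coaflow.circuit import (CircuitState, ElastanceParams, chamber_pressure,
                             coa_net_pg, default_circuit_params,
                             energy_loss_coefficient, mitral_net_pg,
                             normalized_elastance, pulmonary_inflow, simulate,
                             valve_net_pg, assemble_derivatives)
from coaflow.circuit import DegenerateOrificeError
from coaflow.patient import generate_synthetic_patient


class TestElastance:
    def test_value_at_cycle_start_is_e_min(self):
        p = ElastanceParams.lv(0.8)
        assert normalized_elastance(0.0, p) == pytest.approx(p.e_min)

    def test_normalization_constant(self):
        # N = (E_max - E_min)/2 with the ventricular table values
        p = ElastanceParams.lv(1.0)
        assert 0.5 * (p.e_max - p.e_min) == pytest.approx(1.02)

    def test_dense_grid_regression_of_lv_curve(self):
        # frozen from a 1 ms dense-grid evaluation oracle (T = 0.8 s)
        p = ElastanceParams.lv(0.8)
        t = np.arange(0.0, 0.8, 0.001)
        e = np.array([normalized_elastance(ti, p) for ti in t])
        assert e.max() == pytest.approx(0.681681, abs=1e-5)
        assert t[e.argmax()] == pytest.approx(0.313, abs=1e-3)

    def test_periodic_wrap_and_lower_bound(self):
        p = ElastanceParams.la(0.9)
        for t in np.linspace(-2.0, 3.0, 50):
            e = normalized_elastance(t, p)
            assert e >= p.e_min - 1e-12
        assert normalized_elastance(0.9, p) == pytest.approx(
            normalized_elastance(0.0, p))


@pytest.mark.parametrize("e_t, v, v0, expected", [
    (1.0, 60.0, 10.0, 50.0),
    (2.1, 130.0, 10.0, 252.0),
    (0.5, 10.0, 10.0, 0.0),
])
def test_chamber_pressure(e_t, v, v0, expected):
    assert chamber_pressure(e_t, v, v0) == pytest.approx(expected)


class TestEnergyLossCoefficient:
    def test_basic_value(self):
        assert energy_loss_coefficient(2.0, 4.0) == pytest.approx(4.0)

    def test_limits(self):
        assert energy_loss_coefficient(1e-6, 4.0) == pytest.approx(1e-6, rel=1e-3)
        eoa = 2.0
        assert energy_loss_coefficient(eoa, 1e6 * eoa) == pytest.approx(
            eoa, rel=1e-4)
        assert energy_loss_coefficient(2.0, 4.0) > 2.0

    def test_degenerate_orifice_rejected(self):
        with pytest.raises(DegenerateOrificeError):
            energy_loss_coefficient(4.0, 4.0)


class TestPressureGradients:
    def test_zero_flow_zero_gradient(self):
        assert valve_net_pg(0.0, 0.0, 2.0) == 0.0
        assert mitral_net_pg(0.0, 0.0, 4.0) == 0.0
        assert coa_net_pg(0.0, 0.0, 1.0, 3.0) == 0.0

    def test_steady_flow_quadratic(self):
        pg1 = valve_net_pg(150.0, 0.0, 2.0)
        pg2 = valve_net_pg(300.0, 0.0, 2.0)
        assert pg2 == pytest.approx(4.0 * pg1)

    def test_convective_unit_conversion_oracle(self):
        # rho q^2 / (2 elco^2) = 1.05*300^2/8 dyn/cm^2 -> /1333.22 mmHg
        assert valve_net_pg(300.0, 0.0, 2.0, rho=1.05) == pytest.approx(
            8.860128, rel=1e-6)

    def test_mitral_inertance_oracle(self):
        # (0.53/4)*1000 + 1.05/(2*16)*200^2 dyn/cm^2 -> mmHg
        assert mitral_net_pg(200.0, 1000.0, 4.0, m_mv=0.53, rho=1.05) \
            == pytest.approx(1.083842, rel=1e-6)

    def test_mitral_without_inertance_is_convective(self):
        assert mitral_net_pg(200.0, 1000.0, 4.0, m_mv=0.0) == pytest.approx(
            mitral_net_pg(200.0, 0.0, 4.0))

    def test_no_stenosis_limit(self):
        pg = coa_net_pg(300.0, 0.0, 2.999999, 3.0)
        assert abs(pg) < 1e-3

    def test_gradient_monotone_in_orifice_area(self):
        grads = [coa_net_pg(300.0, 0.0, eoa, 3.0)
                 for eoa in np.linspace(0.3, 2.5, 15)]
        assert all(a > b for a, b in zip(grads, grads[1:]))


class TestPulmonaryInflow:
    def test_peak_and_cutoff(self):
        assert pulmonary_inflow(0.15, 400.0, 0.3, 0.8) == pytest.approx(400.0)
        assert pulmonary_inflow(0.3 + 1e-9, 400.0, 0.3, 0.8) == 0.0
        assert pulmonary_inflow(0.79, 400.0, 0.3, 0.8) == 0.0

    def test_cycle_integral_closed_form(self):
        q_mpv, t_ee, T = 433.0, 0.27, 0.8
        t = np.linspace(0, T, 20001)
        q = np.array([pulmonary_inflow(ti, q_mpv, t_ee, T) for ti in t])
        numeric = np.trapezoid(q, t)
        assert numeric == pytest.approx(2 * q_mpv * t_ee / math.pi, rel=1e-6)

    def test_periodicity(self):
        assert pulmonary_inflow(0.9, 400.0, 0.3, 0.8) == pytest.approx(
            pulmonary_inflow(0.1, 400.0, 0.3, 0.8))


class TestDerivatives:
    def test_equilibrium_state_has_zero_flux_derivatives(self):
        params = default_circuit_params()
        v0_lv = params.chambers["lv"].v0
        v0_la = params.chambers["la"].v0
        state = CircuitState(v_lv=v0_lv, v_la=v0_la, p_ao=params.p_cv0,
                             p_sa=params.p_cv0)
        # at t past end-ejection the pulmonary source is silent
        dy = assemble_derivatives(state, 0.99 * params.T, params)
        assert np.allclose(dy, 0.0, atol=1e-12)

    def test_nonfinite_state_raises(self):
        params = default_circuit_params()
        state = CircuitState(v_lv=math.nan, v_la=60, p_ao=70, p_sa=70)
        with pytest.raises(Exception):
            assemble_derivatives(state, 0.1, params)


class TestSimulate:
    def test_no_stenosis_patient_has_negligible_gradient(self):
        rec = generate_synthetic_patient(4, "none", "pre")
        params = default_circuit_params(rec)
        waves = simulate(params, n_cycles=60, stop_when_steady=True)
        from coaflow.metrics import summarize_hemodynamics
        summary = summarize_hemodynamics(waves, params)
        assert summary.peak_gradient < 1.0

    def test_forward_sv_equals_aortic_valve_integral(self, steady_waves):
        params, waves = steady_waves
        fc = waves.final_cycle()
        sv_quad = np.trapezoid(fc.signals["q_av"], fc.time)
        sv_summary = waves.cycle_summary["sv"].iloc[-1]
        assert sv_quad == pytest.approx(sv_summary, rel=2e-3)

    def test_steady_periodicity(self, steady_waves):
        params, waves = steady_waves
        assert waves.steady
        s = waves.cycle_summary
        for col in ("sbp", "dbp", "sv"):
            last, prev = s[col].iloc[-1], s[col].iloc[-2]
            assert abs(last - prev) / abs(prev) < 1e-3

    def test_blood_volume_conservation(self, steady_waves):
        params, waves = steady_waves
        s = waves.cycle_summary.iloc[-1]
        assert s["sv_pv"] == pytest.approx(s["sv_out"], rel=0.01)

    def test_branch_flows_sum_to_aortic_outflow(self, steady_waves):
        params, waves = steady_waves
        s = waves.cycle_summary.iloc[-1]
        assert s["sv"] == pytest.approx(
            s["sv_ub"] + s["sv_coa"] + s["sv_graft"], rel=5e-3)

    def test_compliance_node_flux_balance(self, steady_waves):
        # sum of flows into C_sac equals C dP/dt along the recorded cycle
        params, waves = steady_waves
        fc = waves.final_cycle()
        p_sa = fc.signals["p_sa"]
        influx = (fc.signals["q_ub"] + fc.signals["q_graft"]
                  + fc.signals["q_coa"]
                  - (p_sa - params.p_cv0) / (params.r_sa + params.r_sv))
        dp_dt = np.gradient(p_sa, fc.time)
        resid = influx - params.c_sac * dp_dt
        scale = np.abs(influx).max()
        # interior points only; np.gradient is one-sided at the ends
        assert np.abs(resid[2:-2]).max() / scale < 0.05

    def test_valve_flows_never_negative(self, steady_waves):
        _, waves = steady_waves
        for name in ("q_av", "q_mv", "q_ar", "q_mr"):
            assert waves.signals[name].min() >= 0.0

    def test_removing_graft_reproduces_pre_model_exactly(self):
        rec = generate_synthetic_patient(9, "moderate", "post")
        p_post = default_circuit_params(rec)
        p_off = replace(p_post, graft_present=False, r_graft=0.0)
        rec_pre = replace_state_pre(rec)
        p_pre = default_circuit_params(rec_pre)
        w_off = simulate(p_off, n_cycles=5, stop_when_steady=False)
        w_pre = simulate(p_pre, n_cycles=5, stop_when_steady=False)
        for k in w_pre.signals:
            assert np.array_equal(w_off.signals[k], w_pre.signals[k])

    def test_gradient_monotone_in_coa_area_sweep(self):
        from coaflow.circuit import ValveParams
        from coaflow.metrics import summarize_hemodynamics
        rec = generate_synthetic_patient(3, "moderate", "pre")
        params = default_circuit_params(rec)
        a_down = rec.doppler.a_downstream_coa
        peaks = []
        for ratio in (0.7, 0.45, 0.25):
            valves = dict(params.valves)
            valves["coa"] = ValveParams(ratio * a_down, a_down)
            p = replace(params, valves=valves)
            waves = simulate(p, n_cycles=60, stop_when_steady=True)
            peaks.append(summarize_hemodynamics(waves, p).peak_gradient)
        assert peaks[0] < peaks[1] < peaks[2]


def replace_state_pre(rec):
    from dataclasses import replace as dc_replace
    return dc_replace(rec, state="pre", graft=None)
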