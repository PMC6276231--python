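"""Valves, pump head curve, speed waveforms and the closed loop."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lvadsim.circulation import (
    CirculationState,
    PumpControl,
    PumpParams,
    default_initial_state,
    pump_pressure_head,
    run_to_steady_state,
    set_bai,
    match_map,
    speed_waveform,
    system_rhs,
    valve_flow,
)
from lvadsim.metrics import cycle_metrics
from lvadsim.sarcomere import SarcomereState

VOLUME_SLICE = slice(4, 11)


class TestValveFlow:
    def test_closed_under_reverse_gradient(self):
        assert valve_flow(-20.0, 0.05) == 0.0

    def test_ohmic_forward_conduction(self):
        assert valve_flow(10.0, 0.05) == pytest.approx(200.0, rel=1e-14)

    @given(dp=st.floats(-50, 50))
    def test_continuous_nonnegative_diode(self, dp):
        q = valve_flow(dp, 0.05)
        assert q >= 0.0
        assert valve_flow(dp + 1.0, 0.05) >= q

    def test_invalid_resistance(self):
        with pytest.raises(ValueError):
            valve_flow(1.0, 0.0)


class TestPumpHead:
    def test_stalled_pump_head(self):
        assert pump_pressure_head(0.0, 0.0) == pytest.approx(-15.5)

    def test_direct_substitution_at_speed_100(self):
        # 0.0115·10⁴ + 7.9 − 15.5 = 107.4 mmHg
        assert pump_pressure_head(100.0, 0.0) == pytest.approx(107.4)

    def test_head_droops_with_flow_above_threshold_speed(self):
        # flow coefficient 0.086ω − 0.58 > 0 for ω > ~6.74 R/s
        for omega in (10.0, 100.0, 200.0):
            heads = [pump_pressure_head(omega, q) for q in (0.0, 2.0, 5.0)]
            assert heads[0] > heads[1] > heads[2]

    def test_inertance_term(self):
        p = PumpParams()
        base = pump_pressure_head(100.0, 3.0, 0.0, p)
        assert pump_pressure_head(100.0, 3.0, 2.0, p) == pytest.approx(
            base + p.inertance * 2.0
        )

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            pump_pressure_head(-1.0, 0.0)


class TestSpeedWaveform:
    def test_constant_mode(self):
        c = PumpControl(enabled=True, mode="constant", omega_mean=120.0)
        t = np.linspace(0, 0.8, 33)
        assert np.all(speed_waveform(t, c) == 120.0)

    def test_zero_modulation_reduces_to_constant(self):
        c = PumpControl(enabled=True, mode="co_pulse", omega_mean=120.0,
                        modulation_fraction=0.0)
        assert speed_waveform(0.123, c) == 120.0

    def test_counter_pulse_is_half_period_shift(self):
        co = PumpControl(enabled=True, mode="co_pulse", omega_mean=100.0,
                         modulation_fraction=0.3)
        ct = PumpControl(enabled=True, mode="counter_pulse", omega_mean=100.0,
                         modulation_fraction=0.3)
        t = np.linspace(0, 0.8, 81)
        np.testing.assert_allclose(
            speed_waveform(t, ct), speed_waveform((t - 0.4) % 0.8, co),
            rtol=0, atol=1e-12,
        )

    @pytest.mark.parametrize("mode", ["constant", "co_pulse", "counter_pulse"])
    def test_cycle_mean_equals_omega_mean(self, mode):
        c = PumpControl(enabled=True, mode=mode, omega_mean=130.0,
                        modulation_fraction=0.3)
        t = np.linspace(0, 0.8, 200001)
        w = speed_waveform(t[:-1], c)
        assert w.mean() == pytest.approx(130.0, rel=1e-6)
        assert w.min() >= 0.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            PumpControl(mode="sinusoidal")


class TestSystemRhs:
    def test_volume_derivatives_sum_to_zero(self, params):
        y = default_initial_state(params)
        for t in (0.0, 0.1, 0.33, 0.6):
            d = system_rhs(y, t, params.with_control(enabled=True, omega_mean=120.0))
            assert sum(d[VOLUME_SLICE]) == pytest.approx(0.0, abs=1e-9)
            d = system_rhs(y, t, params.without_pump())
            assert sum(d[VOLUME_SLICE]) == pytest.approx(0.0, abs=1e-9)

    def test_aortic_valve_closed_during_low_lv_pressure(self, params):
        """With the LV relaxed and the aorta pressurised, no aortic-valve
        term appears in the LV volume balance (pure diode)."""
        y = default_initial_state(params)
        d_rest = system_rhs(y, 0.7, params.without_pump())
        # at rest the only LV inflow is mitral; make the mitral gradient
        # negative too and the LV volume must freeze
        state = CirculationState.from_array(y)
        state.v_pu = params.circulation.v0_pu  # pulmonary venous P = 0
        d = system_rhs(state, 0.7, params.without_pump())
        assert d[4] == 0.0
        assert d_rest[4] >= 0.0

    def test_accepts_state_object(self, params):
        state = CirculationState.from_array(default_initial_state(params))
        d = system_rhs(state, 0.0, params)
        assert d.shape == (12,)

    def test_rejects_non_finite_state(self, params):
        y = default_initial_state(params)
        y[4] = np.nan
        with pytest.raises(ValueError):
            system_rhs(y, 0.0, params)


class TestSteadyState:
    def test_healthy_converges_within_50_cycles(self, healthy_sol):
        assert healthy_sol.converged
        assert healthy_sol.n_cycles <= 50

    def test_blood_volume_conserved_over_final_cycle(self, healthy_sol):
        total = healthy_sol.data[
            ["v_lv", "v_ao", "v_art", "v_vc", "v_rv", "v_pa", "v_pu"]
        ].sum(axis=1).to_numpy()
        assert np.ptp(total) / total[0] < 1e-6

    def test_extra_cycle_changes_metrics_marginally(self, params, healthy_sol):
        again = run_to_steady_state(params.without_pump(), y0=healthy_sol.y_final)
        m0, m1 = cycle_metrics(healthy_sol), cycle_metrics(again)
        for name in ("peak_lvp", "systolic_ap", "diastolic_ap", "mean_av_flow",
                     "lv_ew", "edv", "esv"):
            assert getattr(m1, name) == pytest.approx(
                getattr(m0, name), rel=1e-3
            )

    def test_mitral_and_aortic_never_conduct_together(self, healthy_sol):
        df = healthy_sol.data
        assert not np.any((df["q_mt"].to_numpy() > 0) & (df["q_av"].to_numpy() > 0))

    def test_valve_flows_never_negative(self, healthy_sol, hf_sol):
        for sol in (healthy_sol, hf_sol):
            for col in ("q_mt", "q_av", "q_tc", "q_pv"):
                assert sol.data[col].min() >= 0.0

    def test_state_round_trip(self, healthy_sol):
        state = CirculationState.from_array(healthy_sol.y_final)
        np.testing.assert_allclose(state.to_array(), healthy_sol.y_final)
        assert isinstance(state.sarcomere, SarcomereState)
        assert state.total_blood_volume == pytest.approx(
            healthy_sol.y_final[VOLUME_SLICE].sum()
        )


class TestSpeedTuning:
    def test_bai_monotone_in_mean_speed(self, params, hf_sol):
        hf = params.with_ca_max(0.54)
        warm = hf_sol.y_final
        bais = []
        for omega in (70.0, 100.0, 130.0):
            sol = run_to_steady_state(
                hf.with_control(enabled=True, omega_mean=omega), y0=warm
            )
            warm = sol.y_final
            bais.append(cycle_metrics(sol).bai)
        assert bais[0] < bais[1] < bais[2]

    def test_set_bai_hits_target(self, params):
        res = set_bai(0.5, params.with_ca_max(0.54))
        assert abs(res.achieved - 0.5) <= 0.005
        assert res.solution.converged

    def test_match_map_monotone_and_accurate(self, params):
        hf = params.with_ca_max(0.54)
        r1 = match_map(90.0, hf.control, hf)
        r2 = match_map(105.0, hf.control, hf)
        assert abs(r1.achieved - 90.0) <= 0.5
        assert abs(r2.achieved - 105.0) <= 0.5
        assert r2.omega_mean > r1.omega_mean
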