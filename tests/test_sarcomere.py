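"""Calcium transient, troponin kinetics and myofilament force."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from lvadsim.sarcomere import (
    CalciumParams,
    SarcomereParams,
    SarcomereState,
    _calcium_scalar,
    _rhs_scalar,
    calcium_transient,
    sarcomere_force,
    sarcomere_rhs,
)


class TestCalciumTransient:
    @pytest.mark.parametrize(
        "t, literal, expected",
        [
            (0.0, True, 0.1),          # cos(0)=1 collapses the rise branch
            (0.0406, True, 1.57),      # analytic maximum at t1
            (0.5, True, 0.0),          # literal tail after t2
            (0.5, False, 0.1),         # continuous variant holds the baseline
        ],
    )
    def test_pointwise_values(self, t, literal, expected):
        p = CalciumParams(literal_tail=literal)
        assert calcium_transient(t, p) == pytest.approx(expected, abs=1e-12)

    def test_periodicity(self):
        p = CalciumParams()
        t = np.linspace(0.0, 0.8, 97)
        np.testing.assert_allclose(
            calcium_transient(t, p), calcium_transient(t + 3 * p.period, p),
            rtol=0, atol=1e-12,
        )

    @pytest.mark.parametrize("ca_max", [0.54, 0.8, 1.47])
    def test_peak_at_t1_with_amplitude_plus_baseline(self, ca_max):
        p = CalciumParams(ca_max=ca_max)
        grid = np.linspace(0.0, p.period, 80001)
        ca = calcium_transient(grid, p)
        assert ca.max() == pytest.approx(ca_max + p.baseline, rel=1e-8)
        assert grid[ca.argmax()] * 1e3 == pytest.approx(p.t1, abs=0.05)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            calcium_transient(-0.01, CalciumParams())

    @pytest.mark.parametrize(
        "kw", [{"ca_max": -1.0}, {"t1": 200.0, "t2": 130.2},
               {"t2": 900.0}, {"baseline": -0.1}, {"ca_max": math.nan}]
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            CalciumParams(**kw)


class TestKinetics:
    def test_rest_state_is_fixed_point(self):
        p = SarcomereParams()
        l = 1.1
        s = SarcomereState(0.0, 0.0, 0.0, l - p.h_c)
        d = sarcomere_rhs(s, 0.0, l, p)
        assert d.d_tca == d.d_tca_star == d.d_t_star == 0.0
        assert d.d_x == pytest.approx(0.0, abs=1e-10)

    def test_hand_computed_tca_rate(self):
        # [T] = 70 − 10 − 5 − 2 = 53; overlap term = 1 at l = l_a; dX/dt = 0:
        # d[TCa]/dt = 39·53·1 + 1.3·5 − (1.3 + 30)·10 = 1760.5 μM/s
        p = SarcomereParams()
        s = SarcomereState(10.0, 5.0, 2.0, p.l_a - p.h_c)
        d = sarcomere_rhs(s, 1.0, p.l_a, p)
        assert d.d_tca == pytest.approx(1760.5, abs=1e-9)
        assert d.d_x == pytest.approx(0.0, abs=1e-10)

    @given(
        tca=st.floats(0, 20), tca_star=st.floats(0, 20),
        t_star=st.floats(0, 20), ca=st.floats(0, 3),
        l=st.floats(0.8, 1.4),
    )
    def test_bound_pool_rate_balances_free_troponin(self, tca, tca_star, t_star, ca, l):
        """d[TCa]+d[TCa*]+d[T*] = −d[T]/dt: conservation of total troponin."""
        p = SarcomereParams()
        s = SarcomereState(tca, tca_star, t_star, l - p.h_c)
        d = sarcomere_rhs(s, ca, l, p)
        eps = 1e-7
        free0 = p.t_total - (tca + tca_star + t_star)
        free1 = p.t_total - (
            tca + eps * d.d_tca
            + tca_star + eps * d.d_tca_star
            + t_star + eps * d.d_t_star
        )
        d_free = (free1 - free0) / eps
        total = d.d_tca + d.d_tca_star + d.d_t_star
        assert total == pytest.approx(-d_free, rel=1e-5, abs=1e-4)

    def test_invalid_state_rejected(self):
        p = SarcomereParams()
        with pytest.raises(ValueError):
            sarcomere_rhs(SarcomereState(-1.0, 0.0, 0.0, 1.0), 0.1, 1.1, p)
        with pytest.raises(ValueError):
            sarcomere_rhs(SarcomereState(50.0, 30.0, 10.0, 1.0), 0.1, 1.1, p)
        with pytest.raises(ValueError):
            sarcomere_rhs(SarcomereState(0.0, 0.0, 0.0, 1.0), 0.1, -1.0, p)


def _integrate_twitch(ca_max, l=1.15, cycles=3, literal=True):
    cal = CalciumParams(ca_max=ca_max, literal_tail=literal)
    sar = SarcomereParams()

    def rhs(t, y):
        return _rhs_scalar(*y, _calcium_scalar(t % cal.period, cal), l, sar)

    y0 = [0.0, 0.0, 0.0, l - sar.h_c]
    t_end = cycles * cal.period
    grid = np.linspace((cycles - 1) * cal.period, t_end, 801)
    sol = solve_ivp(rhs, (0, t_end), y0, method="LSODA",
                    rtol=1e-9, atol=1e-12, t_eval=grid)
    assert sol.success
    return sol, sar, l


class TestTwitch:
    def test_isometric_relaxation_to_unbound_state(self):
        """With zero calcium at fixed length every pool decays to zero and
        the cross-bridge length settles at L − h_c."""
        sar = SarcomereParams()
        l = 1.1
        y0 = [5.0, 3.0, 1.0, l - 0.02]

        def rhs(t, y):
            return _rhs_scalar(*y, 0.0, l, sar)

        grid = np.linspace(0, 1.0, 501)
        sol = solve_ivp(rhs, (0, 1.0), y0, method="LSODA",
                        rtol=1e-10, atol=1e-13, t_eval=grid)
        bound = sol.y[0] + sol.y[1] + sol.y[2]
        assert np.all(np.diff(bound) < 1e-12)
        assert bound[-1] < 1e-6
        assert sol.y[3, -1] == pytest.approx(l - sar.h_c, abs=1e-9)

    def test_peak_force_monotone_in_calcium_amplitude(self):
        peaks = []
        for ca_max in (0.54, 0.8, 1.47):
            sol, sar, l = _integrate_twitch(ca_max)
            forces = [
                sarcomere_force(SarcomereState(*y), l, sar).total
                for y in sol.y.T
            ]
            peaks.append(max(forces))
        assert peaks[0] < peaks[1] < peaks[2]

    @given(ca_max=st.floats(0.1, 3.0))
    def test_concentrations_stay_admissible(self, ca_max):
        sol, sar, _ = _integrate_twitch(ca_max, cycles=2)
        assert sol.y[:3].min() >= -1e-8
        assert (sol.y[0] + sol.y[1] + sol.y[2]).max() <= sar.t_total + 1e-8


class TestForce:
    def test_no_bound_bridges_no_active_force(self):
        p = SarcomereParams()
        f = sarcomere_force(SarcomereState(5.0, 0.0, 0.0, 1.0), 1.1, p)
        assert f.active == 0.0

    def test_passive_force_vanishes_at_slack_length(self):
        p = SarcomereParams()
        f = sarcomere_force(SarcomereState(0.0, 1.0, 1.0, 1.0), p.l_0, p)
        assert f.passive == pytest.approx(0.0, abs=1e-12)

    def test_direct_active_force_value(self):
        # a_scale = 1, [TCa*]+[T*] = 7 μM, L − X = 0.005 μm → Fa = 0.035
        p = SarcomereParams(a_scale=1.0)
        s = SarcomereState(0.0, 4.0, 3.0, 1.195)
        f = sarcomere_force(s, 1.2, p)
        assert f.active == pytest.approx(0.035, rel=1e-12)
        assert f.total == pytest.approx(f.active + f.passive, rel=1e-12)
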