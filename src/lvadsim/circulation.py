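"""Closed-loop lumped circulation with ventricles, valves and rotary pump.

Eight-part loop: left ventricle (multi-scale: calcium → cross-bridge →
Laplace-law hemisphere), right ventricle (time-varying elastance), aorta,
artery, vena cava, pulmonary artery, pulmonary vein, and the rotary blood
pump.  Four ideal-diode valves (mitral, aortic, tricuspid, pulmonary)
connect the chambers.  Elastic compartments follow P = (V − V0)/C; the
pump head curve is quadratic in speed with a flow-dependent droop and a
blood-inertance term, so pump flow is itself a state variable.

The pump is an intra-aortic device and by default sits *in series* in the
aorta (between the aortic and arterial compartments): raising its speed
lowers the pressure the ventricle ejects against while raising distal
arterial pressure, so aortic-valve flow rises with support level.  A
ventricle-to-aorta ``bypass`` attachment is also available.

State vector (12): [TCa, TCa*, T*, X, V_lv, V_ao, V_art, V_vc, V_rv,
V_pa, V_pu, Q_pump] with volumes in mL and pump flow in L/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .sarcomere import (
    CalciumParams,
    SarcomereParams,
    SarcomereState,
    _calcium_scalar,
    _rhs_scalar,
    calcium_transient,
)
from .ventricle import VentricleGeometry
from .units import MLS_PER_LMIN

__all__ = [
    "CirculationParams",
    "PumpParams",
    "PumpControl",
    "CirculationState",
    "SolverSettings",
    "SystemParams",
    "CycleSolution",
    "BracketError",
    "TuningResult",
    "valve_flow",
    "pump_pressure_head",
    "speed_waveform",
    "rv_elastance",
    "system_rhs",
    "default_initial_state",
    "run_to_steady_state",
    "set_bai",
    "match_map",
]

N_STATES = 12

# convergence scales per state (μM, μM, μM, μm, mL ×7, L/min)
_STATE_SCALE = np.array(
    [0.1, 0.1, 0.1, 0.1, 10.0, 10.0, 10.0, 100.0, 10.0, 10.0, 10.0, 0.5]
)


@dataclass(frozen=True)
class CirculationParams:
    """Compliances (mL/mmHg), unstressed volumes (mL), resistances
    (mmHg·s/mL) and the right-ventricular elastance profile.

    The right ventricle is a time-varying elastance
    E(t) = e_min + (e_max − e_min)·sin²(π t / t_sys) for t < t_sys,
    sharing the cycle period of the calcium transient.
    """

    c_ao: float = 0.55
    c_art: float = 1.8
    c_vc: float = 40.0
    c_pa: float = 4.0
    c_pu: float = 9.0
    v0_ao: float = 70.0
    v0_art: float = 600.0
    v0_vc: float = 2800.0
    v0_pa: float = 120.0
    v0_pu: float = 200.0
    r_prox: float = 0.04
    r_sys: float = 1.3
    r_pul: float = 0.18
    r_mitral: float = 0.04
    r_aortic: float = 0.045
    r_tricuspid: float = 0.024
    r_pulmonic: float = 0.006
    rv_e_max: float = 0.35
    rv_e_min: float = 0.045
    rv_v0: float = 10.0
    rv_t_sys: float = 0.30

    def __post_init__(self) -> None:
        for name in (
            "c_ao", "c_art", "c_vc", "c_pa", "c_pu",
            "r_prox", "r_sys", "r_pul",
            "r_mitral", "r_aortic", "r_tricuspid", "r_pulmonic",
            "rv_e_max", "rv_e_min", "rv_t_sys",
        ):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"CirculationParams.{name} must be positive")


@dataclass(frozen=True)
class PumpParams:
    """Rotary pump head curve and attachment.

    Head (mmHg) = quad_coeff·ω² + lin_coeff·ω + offset
    − (flow_coeff_slope·ω − flow_coeff_intercept)·Q + L_p·dQ/dt,
    with ω in R/s and Q in L/min.  ``inertance`` is L_p in
    mmHg per (L/min)/s.  ``omega_limit`` is a rated threshold speed,
    carried for completeness but not enforced.
    """

    quad_coeff: float = 0.0115
    lin_coeff: float = 0.079
    offset: float = -15.5
    flow_coeff_slope: float = 0.086
    flow_coeff_intercept: float = 0.58
    inertance: float = 0.2
    omega_limit: float = 300.0
    attachment: str = "series"

    def __post_init__(self) -> None:
        if self.inertance <= 0.0:
            raise ValueError("pump inertance must be positive")
        if self.attachment not in ("series", "bypass"):
            raise ValueError("attachment must be 'series' or 'bypass'")


@dataclass(frozen=True)
class PumpControl:
    """Support mode and speed waveform.

    ``mode`` ∈ {constant, co_pulse, counter_pulse}.  Modulated modes add a
    raised-cosine speed pulse of width ``pulse_width`` (s) aligned with
    systole (co_pulse) or shifted by half a cycle (counter_pulse); the
    pulse is mean-centred, so the cycle-average speed equals
    ``omega_mean`` in every mode.
    """

    enabled: bool = False
    mode: str = "constant"
    omega_mean: float = 0.0
    modulation_fraction: float = 0.0
    phase: float = 0.0
    pulse_width: float = 0.1302

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "co_pulse", "counter_pulse"):
            raise ValueError(f"unknown support mode {self.mode!r}")
        if self.omega_mean < 0.0:
            raise ValueError("omega_mean must be non-negative")
        if not 0.0 <= self.modulation_fraction < 1.0:
            raise ValueError("modulation_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class SolverSettings:
    """Stiff-integrator and periodic-steady-state settings."""

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10
    grid_dt: float = 1e-3
    cycle_tol: float = 1e-4
    max_cycles: int = 200


@dataclass(frozen=True)
class SystemParams:
    """Complete parameterisation of the coupled heart–pump–circulation."""

    calcium: CalciumParams = field(default_factory=CalciumParams)
    sarcomere: SarcomereParams = field(default_factory=SarcomereParams)
    geometry: VentricleGeometry = field(default_factory=VentricleGeometry)
    circulation: CirculationParams = field(default_factory=CirculationParams)
    pump: PumpParams = field(default_factory=PumpParams)
    control: PumpControl = field(default_factory=PumpControl)
    solver: SolverSettings = field(default_factory=SolverSettings)
    initial_state: tuple[float, ...] | None = None

    @property
    def period(self) -> float:
        return self.calcium.period

    def with_ca_max(self, ca_max: float) -> "SystemParams":
        return replace(self, calcium=replace(self.calcium, ca_max=ca_max))

    def with_control(self, **kwargs) -> "SystemParams":
        return replace(self, control=replace(self.control, **kwargs))

    def without_pump(self) -> "SystemParams":
        return self.with_control(enabled=False, omega_mean=0.0,
                                 modulation_fraction=0.0, mode="constant")


@dataclass
class CirculationState:
    """Volumes (mL), pump flow (L/min) and the LV sarcomere state."""

    sarcomere: SarcomereState
    v_lv: float
    v_ao: float
    v_art: float
    v_vc: float
    v_rv: float
    v_pa: float
    v_pu: float
    q_pump: float = 0.0

    def to_array(self) -> np.ndarray:
        s = self.sarcomere
        return np.array([
            s.tca, s.tca_star, s.t_star, s.x,
            self.v_lv, self.v_ao, self.v_art, self.v_vc,
            self.v_rv, self.v_pa, self.v_pu, self.q_pump,
        ])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CirculationState":
        y = np.asarray(y, dtype=float)
        if y.shape != (N_STATES,):
            raise ValueError(f"state vector must have length {N_STATES}")
        return cls(
            sarcomere=SarcomereState(y[0], y[1], y[2], y[3]),
            v_lv=y[4], v_ao=y[5], v_art=y[6], v_vc=y[7],
            v_rv=y[8], v_pa=y[9], v_pu=y[10], q_pump=y[11],
        )

    @property
    def total_blood_volume(self) -> float:
        return (self.v_lv + self.v_ao + self.v_art + self.v_vc
                + self.v_rv + self.v_pa + self.v_pu)


class BracketError(RuntimeError):
    """Raised when a speed bracket cannot achieve the requested target."""

    def __init__(self, message: str, achieved_range: tuple[float, float]):
        super().__init__(message)
        self.achieved_range = achieved_range


def valve_flow(delta_p, r_valve: float):
    """Ideal-diode valve: max(ΔP, 0)/R, never negative (mL/s)."""
    if r_valve <= 0.0:
        raise ValueError("valve resistance must be positive")
    return np.maximum(delta_p, 0.0) / r_valve


def pump_pressure_head(omega, q, dq_dt=0.0, p: PumpParams | None = None):
    """Pump pressure head (mmHg) at speed ``omega`` (R/s), flow ``q`` (L/min).

    Includes the inertance term L_p·dQ/dt when a rate of change is given.
    """
    if p is None:
        p = PumpParams()
    if np.any(np.asarray(omega) < 0.0):
        raise ValueError("pump speed must be non-negative")
    return (
        p.quad_coeff * omega**2
        + p.lin_coeff * omega
        + p.offset
        - (p.flow_coeff_slope * omega - p.flow_coeff_intercept) * q
        + p.inertance * dq_dt
    )


def _pulse(tm, width):
    """Mean-one-half raised-cosine pulse on [0, width)."""
    return np.where(tm < width, 0.5 * (1.0 - np.cos(2.0 * np.pi * tm / width)), 0.0)


def speed_waveform(t, c: PumpControl, period: float = 0.8):
    """Pump speed ω(t) (R/s) for the chosen support mode.

    The cycle-mean equals ``omega_mean`` in every mode.
    """
    t_arr = np.asarray(t, dtype=float)
    if c.mode == "constant" or c.modulation_fraction == 0.0:
        out = np.full_like(t_arr, c.omega_mean, dtype=float)
        return float(out) if t_arr.ndim == 0 else out
    shift = 0.0 if c.mode == "co_pulse" else 0.5 * period
    tm = np.mod(t_arr - c.phase - shift, period)
    w = _pulse(tm, c.pulse_width)
    w_mean = 0.5 * c.pulse_width / period
    out = c.omega_mean * (1.0 + c.modulation_fraction * (w - w_mean))
    return float(out) if t_arr.ndim == 0 else out


def rv_elastance(t, c: CirculationParams, period: float = 0.8):
    """Right-ventricular time-varying elastance (mmHg/mL)."""
    tm = np.mod(np.asarray(t, dtype=float), period)
    act = np.where(
        tm < c.rv_t_sys, np.sin(np.pi * tm / c.rv_t_sys) ** 2, 0.0
    )
    out = c.rv_e_min + (c.rv_e_max - c.rv_e_min) * act
    return float(out) if np.asarray(t).ndim == 0 else out


_TWO_THIRDS_PI = 2.0 * math.pi / 3.0


def _make_rhs(sys: SystemParams) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build a fast scalar right-hand side closure for the ODE solver."""
    cal, sar, geo, cir, pmp, ctl = (
        sys.calcium, sys.sarcomere, sys.geometry,
        sys.circulation, sys.pump, sys.control,
    )
    period = cal.period
    l0_over_r0 = geo.l_0 / geo.r_0
    p_scale = sys.geometry.stress_to_pressure * 2.0 * geo.wall_thickness
    series = pmp.attachment == "series"
    pump_on = ctl.enabled
    exp = math.exp
    sin = math.sin
    cos = math.cos
    pi = math.pi
    mf = ctl.modulation_fraction
    pulse_on = ctl.mode != "constant" and mf > 0.0
    shift = ctl.phase + (0.5 * period if ctl.mode == "counter_pulse" else 0.0)
    w_mean = 0.5 * ctl.pulse_width / period

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        tca, tca_s, t_s, x = y[0], y[1], y[2], y[3]
        v_lv, v_ao, v_art, v_vc = y[4], y[5], y[6], y[7]
        v_rv, v_pa, v_pu, q_p = y[8], y[9], y[10], y[11]

        tm = t % period
        ca = _calcium_scalar(tm, cal)

        # left ventricle: volume → radius → length → stress → pressure
        v_pos = v_lv if v_lv > 1e-6 else 1e-6
        r = (v_pos / _TWO_THIRDS_PI) ** (1.0 / 3.0)
        l = l0_over_r0 * r
        d_tca, d_tca_s, d_t_s, dx = _rhs_scalar(tca, tca_s, t_s, x, ca, l, sar)
        fa = sar.a_scale * (tca_s + t_s) * (l - x)
        fp = -sar.k_stiff * (1.0 - l / sar.l_0)
        p_lv = p_scale * (fa + fp) / r

        # elastic compartments
        p_ao = (v_ao - cir.v0_ao) / cir.c_ao
        p_art = (v_art - cir.v0_art) / cir.c_art
        p_vc = (v_vc - cir.v0_vc) / cir.c_vc
        p_pa = (v_pa - cir.v0_pa) / cir.c_pa
        p_pu = (v_pu - cir.v0_pu) / cir.c_pu

        # right ventricle: time-varying elastance
        if tm < cir.rv_t_sys:
            s = sin(pi * tm / cir.rv_t_sys)
            e_rv = cir.rv_e_min + (cir.rv_e_max - cir.rv_e_min) * s * s
        else:
            e_rv = cir.rv_e_min
        p_rv = e_rv * (v_rv - cir.rv_v0)

        # valves (ideal diodes) and linear segments
        q_mt = (p_pu - p_lv) / cir.r_mitral if p_pu > p_lv else 0.0
        q_av = (p_lv - p_ao) / cir.r_aortic if p_lv > p_ao else 0.0
        q_tc = (p_vc - p_rv) / cir.r_tricuspid if p_vc > p_rv else 0.0
        q_pv = (p_rv - p_pa) / cir.r_pulmonic if p_rv > p_pa else 0.0
        q_sys = (p_art - p_vc) / cir.r_sys
        q_pul = (p_pa - p_pu) / cir.r_pul

        dv_lv = q_mt - q_av
        dv_vc = q_sys - q_tc
        dv_rv = q_tc - q_pv
        dv_pa = q_pv - q_pul
        dv_pu = q_pul - q_mt

        if pump_on:
            if pulse_on:
                ts = (t - shift) % period
                if ts < ctl.pulse_width:
                    w = 0.5 * (1.0 - cos(2.0 * pi * ts / ctl.pulse_width))
                else:
                    w = 0.0
                omega = ctl.omega_mean * (1.0 + mf * (w - w_mean))
            else:
                omega = ctl.omega_mean
            head = (
                pmp.quad_coeff * omega * omega
                + pmp.lin_coeff * omega
                + pmp.offset
                - (pmp.flow_coeff_slope * omega - pmp.flow_coeff_intercept) * q_p
            )
            q_p_mls = q_p * MLS_PER_LMIN
            if series:
                dq_p = (p_ao + head - p_art) / pmp.inertance
                dv_ao = q_av - q_p_mls
                dv_art = q_p_mls - q_sys
            else:
                dq_p = (p_lv + head - p_ao) / pmp.inertance
                q_prox = (p_ao - p_art) / cir.r_prox
                dv_lv -= q_p_mls
                dv_ao = q_av + q_p_mls - q_prox
                dv_art = q_prox - q_sys
        else:
            dq_p = 0.0
            q_prox = (p_ao - p_art) / cir.r_prox
            dv_ao = q_av - q_prox
            dv_art = q_prox - q_sys

        return np.array([
            d_tca, d_tca_s, d_t_s, dx,
            dv_lv, dv_ao, dv_art, dv_vc, dv_rv, dv_pa, dv_pu, dq_p,
        ])

    return rhs


def system_rhs(state, t: float, sys: SystemParams) -> np.ndarray:
    """State derivatives of the coupled system at time ``t``.

    ``state`` may be a :class:`CirculationState` or a raw length-12 vector.
    """
    if isinstance(state, CirculationState):
        y = state.to_array()
    else:
        y = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state passed to system_rhs")
    return _make_rhs(sys)(t, y)


def default_initial_state(sys: SystemParams) -> np.ndarray:
    """A physiologically plausible diastolic starting state."""
    if sys.initial_state is not None:
        return np.asarray(sys.initial_state, dtype=float)
    cir = sys.circulation
    v_lv = 120.0
    r = (v_lv / _TWO_THIRDS_PI) ** (1.0 / 3.0)
    l = sys.geometry.l_0 * r / sys.geometry.r_0
    nominal = {
        "ao": 80.0, "art": 80.0, "vc": 5.0, "pa": 15.0, "pu": 10.0,
    }
    return np.array([
        0.02, 0.01, 0.01, l - sys.sarcomere.h_c,
        v_lv,
        cir.v0_ao + cir.c_ao * nominal["ao"],
        cir.v0_art + cir.c_art * nominal["art"],
        cir.v0_vc + cir.c_vc * nominal["vc"],
        100.0,
        cir.v0_pa + cir.c_pa * nominal["pa"],
        cir.v0_pu + cir.c_pu * nominal["pu"],
        0.0,
    ])


@dataclass
class CycleSolution:
    """Converged (or last-attempted) cycle of the closed loop.

    ``data`` holds the dense final-cycle time series on the uniform output
    grid; ``y_final`` the cycle-start state reached, usable as a warm
    start for neighbouring parameter values.
    """

    data: pd.DataFrame
    y_final: np.ndarray
    n_cycles: int
    converged: bool
    residual: float
    params: SystemParams

    @property
    def period(self) -> float:
        return self.params.period


def derived_series(t: np.ndarray, Y: np.ndarray, sys: SystemParams) -> pd.DataFrame:
    """Pressures, flows and forces along a trajectory (vectorised).

    ``Y`` has shape (12, n) as returned by the integrator.
    """
    cal, sar, geo, cir, pmp, ctl = (
        sys.calcium, sys.sarcomere, sys.geometry,
        sys.circulation, sys.pump, sys.control,
    )
    tca, tca_s, t_s, x = Y[0], Y[1], Y[2], Y[3]
    v_lv = np.maximum(Y[4], 1e-6)
    v_ao, v_art, v_vc, v_rv, v_pa, v_pu, q_p = Y[5:12]

    ca = calcium_transient(t, cal)
    r = (v_lv / _TWO_THIRDS_PI) ** (1.0 / 3.0)
    l = geo.l_0 * r / geo.r_0
    fa = sar.a_scale * (tca_s + t_s) * (l - x)
    fp = -sar.k_stiff * (1.0 - l / sar.l_0)
    f = fa + fp
    p_lv = geo.stress_to_pressure * 2.0 * f * geo.wall_thickness / r

    p_ao = (v_ao - cir.v0_ao) / cir.c_ao
    p_art = (v_art - cir.v0_art) / cir.c_art
    p_vc = (v_vc - cir.v0_vc) / cir.c_vc
    p_pa = (v_pa - cir.v0_pa) / cir.c_pa
    p_pu = (v_pu - cir.v0_pu) / cir.c_pu
    p_rv = rv_elastance(t, cir, cal.period) * (v_rv - cir.rv_v0)

    q_mt = valve_flow(p_pu - p_lv, cir.r_mitral)
    q_av = valve_flow(p_lv - p_ao, cir.r_aortic)
    q_tc = valve_flow(p_vc - p_rv, cir.r_tricuspid)
    q_pv = valve_flow(p_rv - p_pa, cir.r_pulmonic)
    q_sys = (p_art - p_vc) / cir.r_sys
    q_pul = (p_pa - p_pu) / cir.r_pul

    if ctl.enabled:
        omega = speed_waveform(t, ctl, cal.period)
        head = pump_pressure_head(omega, q_p, 0.0, pmp)
        q_prox = np.zeros_like(q_sys) if pmp.attachment == "series" else (p_ao - p_art) / cir.r_prox
    else:
        omega = np.zeros_like(np.asarray(t, dtype=float))
        head = np.zeros_like(omega)
        q_prox = (p_ao - p_art) / cir.r_prox

    return pd.DataFrame({
        "time": t, "ca": ca, "omega": omega,
        "p_lv": p_lv, "p_rv": p_rv, "p_ao": p_ao, "p_art": p_art,
        "p_vc": p_vc, "p_pa": p_pa, "p_pu": p_pu,
        "v_lv": Y[4], "v_ao": v_ao, "v_art": v_art, "v_vc": v_vc,
        "v_rv": v_rv, "v_pa": v_pa, "v_pu": v_pu,
        "q_mt": q_mt, "q_av": q_av, "q_tc": q_tc, "q_pv": q_pv,
        "q_sys": q_sys, "q_pul": q_pul, "q_prox": q_prox,
        "q_pump": q_p, "pump_head": head,
        "force_active": fa, "force_passive": fp, "force_total": f,
        "length": l, "radius": r,
    })


def run_to_steady_state(
    sys: SystemParams,
    y0: np.ndarray | None = None,
    max_cycles: int | None = None,
) -> CycleSolution:
    """Integrate cycle by cycle until a periodic steady state is reached.

    Convergence: the maximum scaled change of the cycle-start state between
    successive cycles falls below ``solver.cycle_tol``.  Non-convergence is
    flagged on the returned solution, not raised.
    """
    slv = sys.solver
    if max_cycles is None:
        max_cycles = slv.max_cycles
    period = sys.period
    rhs = _make_rhs(sys)
    y = default_initial_state(sys) if y0 is None else np.asarray(y0, dtype=float)
    if not sys.control.enabled:
        y = y.copy()
        y[11] = 0.0

    residual = math.inf
    converged = False
    n = 0
    for n in range(1, max_cycles + 1):
        sol = solve_ivp(
            rhs, (0.0, period), y, method=slv.method,
            rtol=slv.rtol, atol=slv.atol, dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed in cycle {n}: {sol.message}")
        y_new = sol.y[:, -1]
        residual = float(
            np.max(np.abs(y_new - y) / np.maximum(np.abs(y_new), _STATE_SCALE))
        )
        y = y_new
        if residual < slv.cycle_tol:
            converged = True
            break

    n_pts = int(round(period / slv.grid_dt))
    grid = np.linspace(0.0, period, n_pts + 1)
    sol = solve_ivp(
        rhs, (0.0, period), y, method=slv.method,
        rtol=slv.rtol, atol=slv.atol, t_eval=grid,
    )
    if not sol.success:
        raise RuntimeError(f"dense output integration failed: {sol.message}")
    data = derived_series(grid, sol.y, sys)
    return CycleSolution(
        data=data, y_final=sol.y[:, -1], n_cycles=n,
        converged=converged, residual=residual, params=sys,
    )


@dataclass
class TuningResult:
    """Outcome of a speed-tuning bisection (support level or MAP)."""

    omega_mean: float
    achieved: float
    target: float
    solution: CycleSolution
    iterations: int


def _bisect_speed(
    sys: SystemParams,
    measure: Callable[[CycleSolution], float],
    target: float,
    tol: float,
    bracket: tuple[float, float],
    max_iter: int = 40,
    label: str = "target",
) -> TuningResult:
    """Bisection on omega_mean assuming the measured quantity is monotone
    increasing in speed over the bracket.  Warm-starts each run from the
    previous converged state."""
    lo, hi = bracket
    warm: np.ndarray | None = None

    def run(omega: float) -> tuple[float, CycleSolution]:
        nonlocal warm
        s = sys.with_control(enabled=True, omega_mean=omega)
        sol = run_to_steady_state(s, y0=warm)
        warm = sol.y_final
        return measure(sol), sol

    f_lo, sol_lo = run(lo)
    f_hi, sol_hi = run(hi)
    if not (f_lo <= target <= f_hi):
        raise BracketError(
            f"{label} {target:g} outside achievable range "
            f"[{f_lo:g}, {f_hi:g}] for speeds [{lo:g}, {hi:g}]",
            achieved_range=(f_lo, f_hi),
        )
    best = (abs(f_lo - target), lo, f_lo, sol_lo)
    if abs(f_hi - target) < best[0]:
        best = (abs(f_hi - target), hi, f_hi, sol_hi)
    it = 0
    for it in range(1, max_iter + 1):
        mid = 0.5 * (lo + hi)
        f_mid, sol_mid = run(mid)
        if abs(f_mid - target) < best[0]:
            best = (abs(f_mid - target), mid, f_mid, sol_mid)
        if abs(f_mid - target) <= tol:
            break
        if f_mid < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-3:
            break
    _, omega, achieved, sol = best
    return TuningResult(omega_mean=omega, achieved=achieved, target=target,
                        solution=sol, iterations=it)


def set_bai(
    target_bai: float,
    sys: SystemParams,
    bracket: tuple[float, float] = (45.0, 250.0),
    tol: float = 0.005,
) -> TuningResult:
    """Find the mean pump speed achieving a target blood assist index.

    BAI = pump hydraulic power / (pump + LV power), monotone increasing in
    speed over the bracket.  Achieved BAI is within ±tol of the target.
    """
    if not 0.0 < target_bai < 1.0:
        raise ValueError("target BAI must lie in (0, 1)")
    from .metrics import cycle_metrics

    return _bisect_speed(
        sys, lambda sol: cycle_metrics(sol).bai, target_bai, tol, bracket,
        label="BAI",
    )


def match_map(
    target_map: float,
    control: PumpControl,
    sys: SystemParams,
    bracket: tuple[float, float] = (45.0, 250.0),
    tol: float = 0.5,
) -> TuningResult:
    """Find the mean pump speed giving a target cycle-mean arterial pressure.

    Used to equalise perfusion pressure across support modes before
    comparing them.
    """
    sys = replace(sys, control=replace(control, enabled=True))
    from .metrics import cycle_metrics

    return _bisect_speed(
        sys, lambda sol: cycle_metrics(sol).map, target_map, tol, bracket,
        label="MAP",
    )
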