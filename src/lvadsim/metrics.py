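"""Evaluation indices computed on a converged cardiac cycle.

External work EW = 0.0022/T · ∫ P(t)·Q(t) dt with P in mmHg and Q in
L/min gives watts exactly (1 mmHg·L/min = 2.2×10⁻³ W).  The pulsatile
ratio PR = (max − min)/mean of a pressure waveform is dimensionless.  The
blood assist index BAI = W_pump / (W_pump + W_lv) expresses the fraction
of total hydraulic power delivered by the pump.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .units import MLS_PER_LMIN, WATT_PER_MMHG_LMIN

__all__ = [
    "CycleMetrics",
    "external_work",
    "pulsatile_ratio",
    "blood_assist_index",
    "pv_loop_area",
    "cycle_metrics",
]


def _check_series(*series) -> None:
    n = len(np.asarray(series[0]))
    if n == 0:
        raise ValueError("empty series")
    for s in series[1:]:
        if len(np.asarray(s)) != n:
            raise ValueError("series lengths must match")


def external_work(pressure, flow, period: float) -> float:
    """Cycle-averaged hydraulic power (W).

    ``pressure`` in mmHg and ``flow`` in L/min, sampled uniformly over
    exactly one period (endpoints inclusive).
    """
    _check_series(pressure, flow)
    p = np.asarray(pressure, dtype=float)
    q = np.asarray(flow, dtype=float)
    if len(p) == 1:
        return WATT_PER_MMHG_LMIN * float(p[0] * q[0])
    dt = period / (len(p) - 1)
    return WATT_PER_MMHG_LMIN * float(np.trapezoid(p * q, dx=dt)) / period


def pulsatile_ratio(pressure) -> float:
    """(max − min)/mean of a pressure waveform over one cycle."""
    _check_series(pressure)
    p = np.asarray(pressure, dtype=float)
    mean = float(np.mean(p))
    if mean == 0.0:
        raise ValueError("zero-mean pressure series: pulsatile ratio undefined")
    return float((p.max() - p.min()) / mean)


def blood_assist_index(
    pump_pressure, pump_flow, lv_pressure, cardiac_output, period: float
) -> float:
    """Fraction of total hydraulic power delivered by the pump.

    Both powers are computed with :func:`external_work` on the respective
    pressure/flow pair.  Returns NaN when both powers are zero.
    """
    w_pump = external_work(pump_pressure, pump_flow, period)
    w_lv = external_work(lv_pressure, cardiac_output, period)
    total = w_pump + w_lv
    if total == 0.0:
        return math.nan
    return w_pump / total


def pv_loop_area(volume, pressure) -> float:
    """Signed shoelace area of the pressure–volume loop (mmHg·mL).

    A counter-clockwise (ejecting) loop gives a positive area equal to the
    ventricular stroke work over the cycle.
    """
    _check_series(volume, pressure)
    v = np.asarray(volume, dtype=float)
    p = np.asarray(pressure, dtype=float)
    return float(0.5 * np.sum(v * np.roll(p, -1) - np.roll(v, -1) * p))


@dataclass
class CycleMetrics:
    """Summary indices of one converged cycle."""

    lv_ew: float
    rv_ew: float
    pr_arterial: float
    pr_pulmonary: float
    bai: float
    mean_av_flow: float
    mean_pump_flow: float
    peak_lvp: float
    systolic_ap: float
    diastolic_ap: float
    map: float
    peak_force: float
    edv: float
    esv: float
    pv_area: float
    omega_mean: float
    converged: bool
    pv_loop: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "pv_loop"}
        return d


def cycle_metrics(solution, period: float | None = None) -> CycleMetrics:
    """Compute every cycle index from a converged-cycle solution.

    ``solution`` is a :class:`~lvadsim.circulation.CycleSolution` (or any
    object with a ``data`` DataFrame carrying the standard columns).  If
    the trajectory did not converge the metrics are still computed but
    flagged unreliable via ``converged=False``.
    """
    df = solution.data
    if period is None:
        period = float(solution.period)
    t = df["time"].to_numpy()
    lvp = df["p_lv"].to_numpy()
    rvp = df["p_rv"].to_numpy()
    aop = df["p_ao"].to_numpy()
    ap = df["p_art"].to_numpy()
    pap = df["p_pa"].to_numpy()
    q_av = df["q_av"].to_numpy() / MLS_PER_LMIN       # L/min
    q_pv = df["q_pv"].to_numpy() / MLS_PER_LMIN
    q_pump = df["q_pump"].to_numpy()
    head = df["pump_head"].to_numpy()
    v_lv = df["v_lv"].to_numpy()
    force = df["force_total"].to_numpy()

    lv_ew = external_work(lvp, q_av, period)
    rv_ew = external_work(rvp, q_pv, period)
    w_pump = external_work(head, q_pump, period)
    total = w_pump + lv_ew
    bai = math.nan if total == 0.0 else w_pump / total

    return CycleMetrics(
        lv_ew=lv_ew,
        rv_ew=rv_ew,
        pr_arterial=pulsatile_ratio(ap),
        pr_pulmonary=pulsatile_ratio(pap),
        bai=bai,
        mean_av_flow=float(np.trapezoid(q_av, t) / period),
        mean_pump_flow=float(np.trapezoid(q_pump, t) / period),
        peak_lvp=float(lvp.max()),
        systolic_ap=float(aop.max()),
        diastolic_ap=float(aop.min()),
        map=float(np.trapezoid(ap, t) / period),
        peak_force=float(force.max()),
        edv=float(v_lv.max()),
        esv=float(v_lv.min()),
        pv_area=abs(pv_loop_area(v_lv, lvp)),
        omega_mean=float(solution.params.control.omega_mean
                         if solution.params.control.enabled else 0.0),
        converged=bool(solution.converged),
        pv_loop=np.column_stack([v_lv, lvp]),
    )
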