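"""Calcium-driven troponin / cross-bridge kinetics of the half-sarcomere.

The contractile unit is described by a prescribed intracellular calcium
transient driving a four-state troponin scheme (free troponin T, calcium-
bound TCa, force-generating TCa* and myosin-bound T*) together with a
first-order cross-bridge length state X, in the tradition of the
Negroni–Lascano (1996) cardiac muscle model.  Active stress is proportional
to the force-generating troponin pool times the cross-bridge elongation
(L − X); passive stress is linear in the deviation of the half-sarcomere
length L from its slack value L0.

Units: concentrations μM, lengths μm, rates s⁻¹ (bimolecular rates
μM⁻¹ s⁻¹), stress kPa.  Calcium-transient times are entered in ms, as
conventionally tabulated, and converted once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .units import MS_PER_S

__all__ = [
    "CalciumParams",
    "SarcomereParams",
    "SarcomereState",
    "SarcomereDerivatives",
    "ForceBreakdown",
    "calcium_transient",
    "sarcomere_rhs",
    "sarcomere_force",
]


@dataclass(frozen=True)
class CalciumParams:
    """Piecewise raised-cosine intracellular calcium transient.

    Parameters
    ----------
    ca_max : float
        Transient amplitude above the diastolic baseline, μM.
        1.47 (healthy), 0.54 (heart failure), 0.8 (HF + β-blocker).
    t1 : float
        Time of the calcium peak, ms.
    t2 : float
        Time at which the transient returns to the 0.1 μM diastolic
        level, ms.
    baseline : float
        Diastolic calcium concentration, μM.
    period : float
        Cardiac cycle length, s.
    literal_tail : bool
        If True (default), the concentration is exactly 0 after ``t2``
        (the literal piecewise form, discontinuous by ``baseline`` at t2).
        If False the diastolic baseline is held after t2, keeping the
        transient continuous — but the troponin scheme then retains a
        calcium-bound pool throughout diastole, producing a resting tone
        that prevents ventricular relaxation, so the continuous variant is
        offered only for sensitivity studies.
    """

    ca_max: float = 1.47
    t1: float = 40.6
    t2: float = 130.2
    baseline: float = 0.1
    period: float = 0.8
    literal_tail: bool = True

    def __post_init__(self) -> None:
        for name in ("ca_max", "t1", "t2", "baseline", "period"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"CalciumParams.{name} must be finite, got {v!r}")
        if not 0.0 < self.t1 < self.t2 < self.period * MS_PER_S:
            raise ValueError(
                "require 0 < t1 < t2 < period (t1=%g ms, t2=%g ms, period=%g s)"
                % (self.t1, self.t2, self.period)
            )
        if self.ca_max <= 0.0:
            raise ValueError("ca_max must be positive")
        if self.baseline < 0.0:
            raise ValueError("baseline must be non-negative")


def _calcium_scalar(t: float, p: CalciumParams) -> float:
    """Fast scalar transient; ``t`` in seconds, already within [0, period)."""
    t1 = p.t1 / MS_PER_S
    t2 = p.t2 / MS_PER_S
    if t < t1:
        return 0.5 * p.ca_max * (1.0 - math.cos(math.pi * t / t1)) + p.baseline
    if t < t2:
        return 0.5 * p.ca_max * (1.0 + math.cos(math.pi * (t - t1) / (t2 - t1))) + p.baseline
    return 0.0 if p.literal_tail else p.baseline


def calcium_transient(t, p: CalciumParams):
    """Intracellular calcium concentration at time ``t`` (seconds) in the cycle.

    ``t`` may be a scalar or array; values are taken modulo the cycle
    period, so the transient is periodic.  Negative times are rejected.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("time must be finite")
    if np.any(t_arr < 0.0):
        raise ValueError("time must be non-negative")
    tm = np.mod(t_arr, p.period)
    t1 = p.t1 / MS_PER_S
    t2 = p.t2 / MS_PER_S
    rise = 0.5 * p.ca_max * (1.0 - np.cos(np.pi * tm / t1)) + p.baseline
    fall = 0.5 * p.ca_max * (1.0 + np.cos(np.pi * (tm - t1) / (t2 - t1))) + p.baseline
    tail = 0.0 if p.literal_tail else p.baseline
    out = np.where(tm < t1, rise, np.where(tm < t2, fall, tail))
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class SarcomereParams:
    """Kinetic and mechanical constants of the half-sarcomere.

    Rate constants follow the standard four-state troponin scheme:
    ``y1`` (μM⁻¹ s⁻¹) T + Ca → TCa association, ``z1`` its reverse;
    ``y2`` TCa → TCa* cross-bridge attachment, modulated by the filament
    overlap factor exp(−r_curv (L − l_a)²), ``z2`` its reverse;
    ``y3`` TCa* → T* calcium release from the attached state, ``z3``
    (μM⁻¹ s⁻¹) its calcium-dependent reverse; ``y4`` T* detachment; ``yd``
    (s μm⁻²) velocity-dependent detachment acting on (dX/dt)².

    ``t_total`` is the total troponin concentration (μM); ``b`` (s⁻¹) the
    cross-bridge length relaxation rate; ``h_c`` (μm) the equilibrium
    cross-bridge elongation; ``l_0`` (μm) the slack half-sarcomere length;
    ``l_a`` (μm) the length of maximal thick–thin filament overlap;
    ``r_curv`` (μm⁻²) the overlap curvature; ``a_scale`` (kPa μM⁻¹ μm⁻¹)
    the active-stress scale and ``k_stiff`` (kPa) the passive stiffness.

    ``a_scale``, ``k_stiff``, ``r_curv`` and ``l_a`` are not part of the
    tabulated kinetic set and are exposed for calibration.
    """

    y1: float = 39.0
    z1: float = 30.0
    y2: float = 1.3
    z2: float = 1.3
    y3: float = 30.0
    z3: float = 1560.0
    y4: float = 40.0
    yd: float = 8.0
    t_total: float = 70.0
    b: float = 800.0
    h_c: float = 0.005
    l_0: float = 1.17
    l_a: float = 1.17
    r_curv: float = 5.0
    a_scale: float = 8500.0
    k_stiff: float = 80.0

    def __post_init__(self) -> None:
        rates = ("y1", "z1", "y2", "z2", "y3", "z3", "y4", "yd", "b")
        for name in rates:
            if getattr(self, name) < 0.0:
                raise ValueError(f"rate {name} must be non-negative")
        if self.t_total <= 0.0:
            raise ValueError("t_total must be positive")
        if not 0.0 < self.h_c < self.l_0:
            raise ValueError("require 0 < h_c < l_0")


@dataclass
class SarcomereState:
    """Troponin pool concentrations (μM) and cross-bridge length X (μm)."""

    tca: float
    tca_star: float
    t_star: float
    x: float

    def validate(self, p: SarcomereParams) -> None:
        if min(self.tca, self.tca_star, self.t_star) < 0.0:
            raise ValueError("troponin pools must be non-negative")
        if self.tca + self.tca_star + self.t_star > p.t_total * (1.0 + 1e-12):
            raise ValueError("bound troponin exceeds total troponin")

    def free_troponin(self, p: SarcomereParams) -> float:
        """[T] = T_t − [T*] − [TCa] − [TCa*] (conservation closure)."""
        return p.t_total - self.tca - self.tca_star - self.t_star


class SarcomereDerivatives(NamedTuple):
    d_tca: float
    d_tca_star: float
    d_t_star: float
    d_x: float


class ForceBreakdown(NamedTuple):
    active: float
    passive: float
    total: float


def sarcomere_rhs(
    s: SarcomereState, ca: float, l: float, p: SarcomereParams
) -> SarcomereDerivatives:
    """Time derivatives of the troponin pools and cross-bridge length.

    ``ca`` is the instantaneous calcium concentration (μM) and ``l`` the
    half-sarcomere length (μm).  dX/dt = b·(L − X − h_c) is evaluated
    first and its square feeds the velocity-dependent detachment terms,
    keeping the right-hand side a pure function of state.
    """
    if l <= 0.0:
        raise ValueError("half-sarcomere length must be positive")
    s.validate(p)
    return SarcomereDerivatives(
        *_rhs_scalar(s.tca, s.tca_star, s.t_star, s.x, ca, l, p)
    )


def _rhs_scalar(tca, tca_star, t_star, x, ca, l, p: SarcomereParams):
    """Unchecked scalar kernel shared with the closed-loop ODE."""
    dx = p.b * (l - x - p.h_c)
    dx2 = p.yd * dx * dx
    dl = l - p.l_a
    overlap = math.exp(-p.r_curv * dl * dl)
    t_free = p.t_total - tca - tca_star - t_star
    d_tca = p.y1 * t_free * ca + p.z2 * tca_star - (p.y2 * overlap + p.z1) * tca
    d_tca_star = (
        p.y2 * overlap * tca
        + p.z3 * t_star * ca
        - (p.z2 + dx2 + p.y3) * tca_star
    )
    d_t_star = p.y3 * tca_star - (p.z3 * ca + p.y4 + dx2) * t_star
    return d_tca, d_tca_star, d_t_star, dx


def sarcomere_force(s: SarcomereState, l: float, p: SarcomereParams) -> ForceBreakdown:
    """Active, passive and total myofilament stress (kPa) at length ``l``.

    Active stress is a_scale·([TCa*] + [T*])·(L − X); passive stress is
    −k_stiff·(1 − L/L0), i.e. tensile above slack length and compressive
    below it.
    """
    if l <= 0.0:
        raise ValueError("half-sarcomere length must be positive")
    fa = p.a_scale * (s.tca_star + s.t_star) * (l - s.x)
    fp = -p.k_stiff * (1.0 - l / p.l_0)
    return ForceBreakdown(fa, fp, fa + fp)
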