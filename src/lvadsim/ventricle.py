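"""Hemispherical Laplace-law ventricle.

The chamber is a thin-walled hemisphere of constant wall thickness h.
Chamber volume maps to mid-wall radius through V = (2/3)πR³, radius maps
linearly to half-sarcomere length through L/L0 = R/R0, and wall stress F
maps to cavity pressure through the Laplace relation P = 2 F h / R.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .units import MMHG_PER_KPA

__all__ = [
    "VentricleGeometry",
    "volume_from_radius",
    "radius_from_volume",
    "length_from_radius",
    "length_rate",
    "pressure_from_force",
]

_TWO_THIRDS_PI = 2.0 * math.pi / 3.0


@dataclass(frozen=True)
class VentricleGeometry:
    """Geometry of the hemispherical chamber.

    wall_thickness (cm), r_0 unstressed radius (cm), l_0 unstressed
    half-sarcomere length (μm), and the stress→pressure conversion factor
    (mmHg per kPa of wall stress; 1 kPa = 7.50062 mmHg).
    """

    wall_thickness: float = 1.0
    r_0: float = 3.5
    l_0: float = 1.17
    stress_to_pressure: float = MMHG_PER_KPA

    def __post_init__(self) -> None:
        if self.wall_thickness <= 0.0 or self.r_0 <= 0.0 or self.l_0 <= 0.0:
            raise ValueError("geometry lengths must be positive")


def volume_from_radius(r: float, g: VentricleGeometry | None = None) -> float:
    """Hemisphere volume (mL) for mid-wall radius ``r`` (cm)."""
    if r < 0.0:
        raise ValueError("radius must be non-negative")
    return _TWO_THIRDS_PI * r**3


def radius_from_volume(v: float, g: VentricleGeometry | None = None) -> float:
    """Mid-wall radius (cm) of a hemisphere holding volume ``v`` (mL)."""
    if v < 0.0:
        raise ValueError("volume must be non-negative")
    return (v / _TWO_THIRDS_PI) ** (1.0 / 3.0)


def length_from_radius(r: float, g: VentricleGeometry) -> float:
    """Half-sarcomere length (μm): L = l_0 · r / r_0."""
    if r <= 0.0:
        raise ValueError("radius must be positive")
    return g.l_0 * r / g.r_0


def length_rate(r: float, dv_dt: float, g: VentricleGeometry) -> float:
    """dL/dt (μm/s) by the chain rule given dV/dt (mL/s) at radius ``r``.

    dL/dt = (l_0/r_0) · dR/dV · dV/dt with dR/dV = 1/(2πR²).
    """
    if r <= 0.0:
        raise ValueError("radius must be positive")
    return (g.l_0 / g.r_0) * dv_dt / (2.0 * math.pi * r * r)


def pressure_from_force(f: float, r: float, g: VentricleGeometry) -> float:
    """Cavity pressure (mmHg) from wall stress ``f`` (kPa) at radius ``r`` (cm).

    P = stress_to_pressure · 2 f h / r.
    """
    if r <= 0.0:
        raise ValueError("radius must be positive")
    return g.stress_to_pressure * 2.0 * f * g.wall_thickness / r
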