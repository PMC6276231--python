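"""End-to-end experiments: support-level sweep, support-mode comparison,
β-blocker coupling, and the baseline calibration.

Disease states are pure calcium substitutions (peak intracellular calcium
1.47 μM healthy, 0.54 μM heart failure, 0.8 μM HF + β-blocker); the
β-blockers modelled act on calcium cycling only, with no peripheral
vascular effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import config as _config
from .circulation import (
    BracketError,
    SystemParams,
    match_map,
    run_to_steady_state,
    set_bai,
)
from .metrics import cycle_metrics
from .model import DISEASE_CA_MAX

__all__ = [
    "ScenarioSpec",
    "build_params",
    "run_bai_sweep",
    "run_mode_comparison",
    "run_drug_coupling",
    "calibrate_baseline",
    "DEFAULT_TARGETS",
    "DEFAULT_FREE_PARAMETERS",
    "DEFAULT_BOUNDS",
]


@dataclass
class ScenarioSpec:
    """One named simulation scenario.

    ``support`` is either None (unassisted), ``{"bai": fraction}`` or
    ``{"mode": ..., "map_target": mmHg}``; ``overrides`` are dotted-path
    parameter patches applied last.
    """

    name: str
    disease_state: str = "healthy"
    support: Mapping | None = None
    overrides: Mapping = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.disease_state not in DISEASE_CA_MAX:
            raise ValueError(f"unknown disease state {self.disease_state!r}")
        if self.support is not None and not (
            ("bai" in self.support) ^ ("map_target" in self.support)
        ):
            raise ValueError("support must specify exactly one of bai / map_target")


def build_params(spec: ScenarioSpec, base: SystemParams | None = None) -> SystemParams:
    """Parameter set for a scenario, before any speed tuning."""
    params = base if base is not None else _config.default_params()
    params = params.with_ca_max(DISEASE_CA_MAX[spec.disease_state])
    if spec.support is None:
        params = params.without_pump()
    elif "mode" in (spec.support or {}):
        params = params.with_control(enabled=True, mode=spec.support["mode"])
    if spec.overrides:
        params = _config.apply_overrides(params, spec.overrides)
    return params


def _metrics_row(sol, **extra) -> dict:
    row = cycle_metrics(sol).to_dict()
    row.update(extra)
    return row


def run_bai_sweep(
    levels: Sequence[float],
    disease_state: str = "hf",
    base_params: SystemParams | None = None,
    modulation_fraction: float = 0.0,
    mode: str = "constant",
) -> pd.DataFrame:
    """Unassisted baseline plus one converged run per support level.

    Levels are blood-assist-index fractions in (0, 1); the pump runs at
    constant speed by default.  Rows are ordered baseline first, then by
    increasing level; a level whose speed bisection fails is flagged
    (``converged=False``) and the sweep continues.
    """
    levels = sorted(levels)
    if any(not 0.0 < b < 1.0 for b in levels):
        raise ValueError("levels must lie in (0, 1)")
    base = base_params if base_params is not None else _config.default_params()
    base = base.with_ca_max(DISEASE_CA_MAX[disease_state])

    rows = []
    sol0 = run_to_steady_state(base.without_pump())
    rows.append(_metrics_row(sol0, bai_target=0.0, scenario="baseline"))

    assisted = base.with_control(
        enabled=True, mode=mode, modulation_fraction=modulation_fraction
    )
    lo = 45.0
    for level in levels:
        try:
            res = set_bai(level, assisted, bracket=(lo, 250.0))
        except BracketError as err:
            rows.append({"bai_target": level, "scenario": f"bai_{level:.2f}",
                         "converged": False, "error": str(err)})
            continue
        rows.append(_metrics_row(res.solution, bai_target=level,
                                 scenario=f"bai_{level:.2f}"))
        lo = max(45.0, res.omega_mean - 1.0)  # BAI monotone in speed
    return pd.DataFrame(rows)


_MODES = ("constant", "co_pulse", "counter_pulse")


def run_mode_comparison(
    map_target: float = 98.0,
    disease_state: str = "hf",
    with_drug: bool = False,
    base_params: SystemParams | None = None,
    modulation_fraction: float = 0.3,
    modes: Sequence[str] = _MODES,
) -> pd.DataFrame:
    """Compare support modes at equal perfusion pressure.

    Each mode's mean speed is tuned so the cycle-mean arterial pressure
    equals ``map_target``.  With ``with_drug`` a paired run per mode adds
    the β-blocker (peak calcium 0.54 → 0.8 μM) at the *same* tuned speed,
    modelling drug addition without re-tuning the pump.
    """
    base = base_params if base_params is not None else _config.default_params()
    hf = base.with_ca_max(DISEASE_CA_MAX[disease_state])
    rows = []
    for m in modes:
        control = hf.control.__class__(
            enabled=True, mode=m,
            modulation_fraction=0.0 if m == "constant" else modulation_fraction,
        )
        try:
            res = match_map(map_target, control, hf)
        except BracketError as err:
            raise BracketError(
                f"mode {m!r}: {err}", err.achieved_range
            ) from err
        rows.append(_metrics_row(res.solution, mode=m, drug=False,
                                 map_target=map_target))
        if with_drug:
            drugged = res.solution.params.with_ca_max(
                DISEASE_CA_MAX["hf_beta_blocker"]
            )
            sol_d = run_to_steady_state(drugged, y0=res.solution.y_final)
            rows.append(_metrics_row(sol_d, mode=m, drug=True,
                                     map_target=map_target))
    return pd.DataFrame(rows)


def run_drug_coupling(
    modes: Sequence[str] = _MODES,
    map_target: float = 98.0,
    base_params: SystemParams | None = None,
    modulation_fraction: float = 0.3,
) -> pd.DataFrame:
    """Paired LVAD vs LVAD + β-blocker table per support mode."""
    return run_mode_comparison(
        map_target=map_target, disease_state="hf", with_drug=True,
        base_params=base_params, modulation_fraction=modulation_fraction,
        modes=modes,
    )


#: Printed waveform values the shipped default set is calibrated against.
DEFAULT_TARGETS = (
    {"metric": "peak_lvp", "value": 110.0, "weight": 1.0,
     "scenario": "healthy", "tol": 2.0},
    {"metric": "systolic_ap", "value": 95.0, "weight": 1.0,
     "scenario": "healthy", "tol": 2.0},
    {"metric": "diastolic_ap", "value": 70.0, "weight": 1.0,
     "scenario": "healthy", "tol": 2.0},
    {"metric": "mean_av_flow", "value": 2.87, "weight": 2.0,
     "scenario": "hf", "tol": 0.29},
)

DEFAULT_FREE_PARAMETERS = (
    "sarcomere.a_scale",
    "sarcomere.k_stiff",
    "geometry.r_0",
    "circulation.r_sys",
)

DEFAULT_BOUNDS = {
    "sarcomere.a_scale": (500.0, 20000.0),
    "sarcomere.k_stiff": (1.0, 250.0),
    "geometry.r_0": (2.2, 4.5),
    "circulation.r_sys": (0.4, 2.5),
    "circulation.c_ao": (0.2, 3.0),
    "circulation.c_art": (0.5, 6.0),
    "geometry.wall_thickness": (0.5, 2.0),
}


def calibrate_baseline(
    targets: Sequence[Mapping] | None = None,
    free_parameters: Sequence[str] | None = None,
    bounds: Mapping[str, tuple] | None = None,
    base_params: SystemParams | None = None,
    maxiter: int = 200,
    out_path=None,
):
    """Bounded Nelder–Mead fit of free constants to waveform targets.

    Targets are ``{"metric", "value", "weight", "scenario", "tol"}`` dicts;
    metrics are cycle-metric field names evaluated on the unassisted
    converged cycle of the named disease state.  Deterministic given a
    fixed starting point (no stochastic restarts).  If a target misses its
    tolerance the report is marked failed but the fitted parameters are
    still returned (and written when ``out_path`` is given).
    """
    from .model import CalibrationResults

    targets = list(targets) if targets is not None else [dict(t) for t in DEFAULT_TARGETS]
    free = list(free_parameters) if free_parameters is not None else list(DEFAULT_FREE_PARAMETERS)
    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    base = base_params if base_params is not None else _config.default_params()

    scenarios = sorted({t.get("scenario", "healthy") for t in targets})
    warm: dict[str, np.ndarray] = {}

    def measure(params: SystemParams) -> dict[str, object]:
        out = {}
        for sc in scenarios:
            p = params.with_ca_max(DISEASE_CA_MAX[sc]).without_pump()
            sol = run_to_steady_state(p, y0=warm.get(sc))
            warm[sc] = sol.y_final
            out[sc] = cycle_metrics(sol)
        return out

    def achieved(metrics_by_scenario, t) -> float:
        m = metrics_by_scenario[t.get("scenario", "healthy")]
        return float(getattr(m, t["metric"]))

    if not free:
        mets = measure(base)
        report = _calibration_report(base, targets, mets, achieved,
                                     objective=0.0, iterations=0, fitted={})
        result = CalibrationResults(base, report)
        if out_path is not None:
            _config.dump_params(base, out_path)
        return result

    x0 = np.array([_get_path(base, name) for name in free])

    def objective(x: np.ndarray) -> float:
        params = _config.apply_overrides(base, dict(zip(free, x)))
        mets = measure(params)
        return sum(
            t.get("weight", 1.0) * ((achieved(mets, t) - t["value"]) / t["value"]) ** 2
            for t in targets
        )

    res = minimize(
        objective, x0, method="Nelder-Mead",
        bounds=[bnds[name] for name in free],
        options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-8,
                 "adaptive": True},
    )
    fitted = dict(zip(free, (float(v) for v in res.x)))
    params = _config.apply_overrides(base, fitted)
    mets = measure(params)
    report = _calibration_report(params, targets, mets, achieved,
                                 objective=float(res.fun),
                                 iterations=int(res.nit), fitted=fitted)
    result = CalibrationResults(params, report)
    if out_path is not None:
        _config.dump_params(params, out_path)
    return result


def _get_path(params: SystemParams, name: str) -> float:
    section, _, fname = name.partition(".")
    return float(getattr(getattr(params, section), fname))


def _calibration_report(params, targets, mets, achieved, objective,
                        iterations, fitted) -> dict:
    rows = []
    ok = True
    for t in targets:
        a = achieved(mets, t)
        tol = t.get("tol", 0.05 * abs(t["value"]))
        hit = abs(a - t["value"]) <= tol
        ok = ok and hit
        rows.append({**{k: t[k] for k in ("metric", "value")},
                     "scenario": t.get("scenario", "healthy"),
                     "achieved": a, "tol": tol, "within_tol": hit})
    return {
        "success": ok,
        "objective": objective,
        "iterations": iterations,
        "fitted": fitted,
        "targets": rows,
        "config_hash": _config.config_hash(params),
    }
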