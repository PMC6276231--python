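"""Model/Results facade over the closed-loop simulator.

`HeartPumpModel` bundles a complete parameter set (defaulting to the
shipped calibrated set) with a disease state and a support configuration.
``simulate()`` integrates to the periodic steady state and returns a
:class:`SimulationResults` carrying the dense final cycle, its metrics and
a text summary; ``fit()`` runs the bounded Nelder–Mead calibration of free
constants against waveform targets and returns a
:class:`CalibrationResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import config as _config
from .circulation import (
    CycleSolution,
    SystemParams,
    TuningResult,
    match_map,
    run_to_steady_state,
    set_bai,
)
from .metrics import CycleMetrics, cycle_metrics

__all__ = ["HeartPumpModel", "SimulationResults", "CalibrationResults",
           "DISEASE_CA_MAX"]

#: Peak-calcium mapping of the modelled disease states (μM).
DISEASE_CA_MAX = {"healthy": 1.47, "hf": 0.54, "hf_beta_blocker": 0.8}


class HeartPumpModel:
    """Coupled heart–pump–circulation model at a fixed parameter set."""

    def __init__(self, params: SystemParams | None = None):
        self.params = params if params is not None else _config.default_params()

    @classmethod
    def from_config(cls, path) -> "HeartPumpModel":
        return cls(_config.load_params(path))

    @classmethod
    def from_disease_state(
        cls,
        disease_state: str = "healthy",
        params: SystemParams | None = None,
        overrides: Mapping | None = None,
    ) -> "HeartPumpModel":
        """Build a model for one of the named disease states.

        Disease states differ only in peak intracellular calcium:
        healthy 1.47 μM, heart failure 0.54 μM, HF + β-blocker 0.8 μM.
        """
        if disease_state not in DISEASE_CA_MAX:
            raise ValueError(f"unknown disease state {disease_state!r}")
        base = params if params is not None else _config.default_params()
        base = base.with_ca_max(DISEASE_CA_MAX[disease_state])
        if overrides:
            base = _config.apply_overrides(base, overrides)
        return cls(base)

    def simulate(self, y0: np.ndarray | None = None,
                 max_cycles: int | None = None) -> "SimulationResults":
        """Run to periodic steady state and return the converged cycle."""
        sol = run_to_steady_state(self.params, y0=y0, max_cycles=max_cycles)
        return SimulationResults(sol)

    def with_support_level(self, bai: float, **kw) -> "TuningResult":
        """Tune mean pump speed to a blood-assist-index target."""
        return set_bai(bai, self.params, **kw)

    def with_matched_map(self, map_target: float, **kw) -> "TuningResult":
        """Tune mean pump speed to a mean-arterial-pressure target."""
        return match_map(map_target, self.params.control, self.params, **kw)

    def fit(
        self,
        targets: Sequence[Mapping] | None = None,
        free_parameters: Sequence[str] | None = None,
        bounds: Mapping[str, tuple] | None = None,
        **kw,
    ) -> "CalibrationResults":
        """Calibrate free constants against waveform targets.

        Thin wrapper over :func:`lvadsim.scenarios.calibrate_baseline`;
        with no arguments it re-runs the standard baseline calibration
        from the current parameter set.
        """
        from .scenarios import calibrate_baseline

        return calibrate_baseline(
            targets=targets, free_parameters=free_parameters, bounds=bounds,
            base_params=self.params, **kw,
        )


class SimulationResults:
    """Converged-cycle results: dense waveforms, metrics, summary, plots."""

    def __init__(self, solution: CycleSolution):
        self.solution = solution
        self._metrics: CycleMetrics | None = None

    @property
    def trajectory(self) -> pd.DataFrame:
        return self.solution.data

    @property
    def converged(self) -> bool:
        return self.solution.converged

    @property
    def n_cycles(self) -> int:
        return self.solution.n_cycles

    @property
    def metrics(self) -> CycleMetrics:
        if self._metrics is None:
            self._metrics = cycle_metrics(self.solution)
        return self._metrics

    def summary(self) -> str:
        m = self.metrics
        ctl = self.solution.params.control
        lines = [
            "Closed-loop cardiac cycle summary",
            "=" * 44,
            f"converged            {self.converged} ({self.n_cycles} cycles, "
            f"residual {self.solution.residual:.2e})",
            f"support              "
            + (f"{ctl.mode}, mean speed {ctl.omega_mean:.1f} R/s"
               if ctl.enabled else "none"),
            f"peak LVP             {m.peak_lvp:8.1f} mmHg",
            f"aortic sys/dia       {m.systolic_ap:5.1f}/{m.diastolic_ap:5.1f} mmHg",
            f"mean arterial P      {m.map:8.1f} mmHg",
            f"mean AV flow         {m.mean_av_flow:8.2f} L/min",
            f"mean pump flow       {m.mean_pump_flow:8.2f} L/min",
            f"LV / RV ext. work    {m.lv_ew:6.3f} / {m.rv_ew:6.3f} W",
            f"PR arterial / pulm.  {m.pr_arterial:6.3f} / {m.pr_pulmonary:6.3f}",
            f"blood assist index   {m.bai:8.3f}" if np.isfinite(m.bai)
            else "blood assist index        n/a",
            f"peak wall stress     {m.peak_force:8.2f} kPa",
            f"LV EDV / ESV         {m.edv:6.1f} / {m.esv:6.1f} mL",
            f"PV-loop area         {m.pv_area:8.1f} mmHg·mL",
        ]
        return "\n".join(lines)

    def plot_pv_loop(self, ax=None, **kw):
        """Left-ventricular pressure–volume loop of the converged cycle."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.trajectory
        ax.plot(df["v_lv"], df["p_lv"], **kw)
        ax.set_xlabel("LV volume (mL)")
        ax.set_ylabel("LV pressure (mmHg)")
        return ax

    def plot_waveforms(self, axes=None):
        """Pressures, flows and speed over the converged cycle."""
        import matplotlib.pyplot as plt

        df = self.trajectory
        if axes is None:
            _, axes = plt.subplots(3, 1, sharex=True, figsize=(7, 8))
        axes[0].plot(df["time"], df["p_lv"], label="LVP")
        axes[0].plot(df["time"], df["p_ao"], label="AoP")
        axes[0].plot(df["time"], df["p_art"], label="AP")
        axes[0].set_ylabel("pressure (mmHg)")
        axes[0].legend(loc="upper right", fontsize="small")
        axes[1].plot(df["time"], df["q_av"], label="aortic valve")
        axes[1].plot(df["time"], df["q_mt"], label="mitral valve")
        axes[1].set_ylabel("flow (mL/s)")
        axes[1].legend(loc="upper right", fontsize="small")
        axes[2].plot(df["time"], df["omega"], label="pump speed")
        axes[2].set_ylabel("speed (R/s)")
        axes[2].set_xlabel("time in cycle (s)")
        return axes


@dataclass
class CalibrationResults:
    """Calibrated parameter set plus the fit report."""

    params: SystemParams
    report: dict

    @property
    def success(self) -> bool:
        return bool(self.report.get("success", False))

    def summary(self) -> str:
        rep = self.report
        lines = [
            "Baseline calibration",
            "=" * 44,
            f"success              {rep['success']}",
            f"objective            {rep['objective']:.4g}",
            f"iterations           {rep['iterations']}",
        ]
        for t in rep["targets"]:
            lines.append(
                f"  {t['metric']:<22s} target {t['value']:8.2f}  "
                f"achieved {t['achieved']:8.2f}"
            )
        for name, value in rep["fitted"].items():
            lines.append(f"  {name:<22s} = {value:.6g}")
        return "\n".join(lines)
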