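"""Parameter-set serialisation and the shipped calibrated defaults.

A :class:`~lvadsim.circulation.SystemParams` round-trips through a plain
nested dict, written as YAML or JSON.  Dotted-path overrides
(``"sarcomere.a_scale"``) patch individual constants, which is how disease
states, scenario files and the calibrator modify the versioned default
parameter set shipped with the package.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .circulation import (
    CirculationParams,
    PumpControl,
    PumpParams,
    SolverSettings,
    SystemParams,
)
from .sarcomere import CalciumParams, SarcomereParams
from .ventricle import VentricleGeometry

__all__ = [
    "params_to_dict",
    "params_from_dict",
    "load_params",
    "dump_params",
    "apply_overrides",
    "default_params",
    "config_hash",
]

_SECTIONS = {
    "calcium": CalciumParams,
    "sarcomere": SarcomereParams,
    "geometry": VentricleGeometry,
    "circulation": CirculationParams,
    "pump": PumpParams,
    "control": PumpControl,
    "solver": SolverSettings,
}


def params_to_dict(params: SystemParams) -> dict:
    d: dict[str, Any] = {
        name: dataclasses.asdict(getattr(params, name)) for name in _SECTIONS
    }
    if params.initial_state is not None:
        d["initial_state"] = [float(v) for v in params.initial_state]
    return d


def params_from_dict(d: Mapping[str, Any]) -> SystemParams:
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        if name in d:
            kwargs[name] = cls(**d[name])
    if d.get("initial_state") is not None:
        kwargs["initial_state"] = tuple(float(v) for v in d["initial_state"])
    return SystemParams(**kwargs)


def load_params(path: str | Path) -> SystemParams:
    """Read a parameter set from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return params_from_dict(data)


def dump_params(params: SystemParams, path: str | Path) -> None:
    """Write a parameter set; the format follows the file extension."""
    path = Path(path)
    d = params_to_dict(params)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))


def apply_overrides(params: SystemParams, overrides: Mapping[str, Any]) -> SystemParams:
    """Return a copy with dotted-path fields replaced.

    Example: ``apply_overrides(p, {"calcium.ca_max": 0.54,
    "control.mode": "co_pulse"})``.
    """
    for key, value in overrides.items():
        section, _, fname = key.partition(".")
        if section not in _SECTIONS or not fname:
            raise KeyError(f"unknown parameter path {key!r}")
        block = getattr(params, section)
        if not hasattr(block, fname):
            raise KeyError(f"unknown parameter path {key!r}")
        params = dataclasses.replace(
            params, **{section: dataclasses.replace(block, **{fname: value})}
        )
    return params


def default_params() -> SystemParams:
    """The calibrated default parameter set shipped with the package."""
    with resources.files("lvadsim.params").joinpath("default_params.json").open() as fh:
        return params_from_dict(json.load(fh))


def config_hash(params: SystemParams) -> str:
    """SHA-256 of the canonical JSON form, for run manifests."""
    blob = json.dumps(params_to_dict(params), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
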