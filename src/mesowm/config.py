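"""Configuration loading, validation and persistence (YAML/JSON)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import yaml

from .params import ModelParameters, W34_BASELINE, paper_defaults
from .simulate import SimulationSettings

__all__ = ["RunConfig", "load_config", "save_config"]

_PARAM_KEYS = {f.name for f in fields(ModelParameters)}
_SIM_KEYS = {f.name for f in fields(SimulationSettings)}
_SWEEP_KEYS = {"lo_percent", "hi_percent", "step_percent", "percents"}
_TOP_KEYS = {"profile", "task", "parameters", "simulation", "sweep",
             "acknowledge_d_max_default"}


@dataclass(frozen=True)
class RunConfig:
    """Validated bundle of model parameters, settings and a sweep spec."""

    params: ModelParameters
    settings: SimulationSettings
    sweep_percents: Optional[np.ndarray] = None
    task: Optional[str] = None

    def sweep_w34(self) -> Optional[np.ndarray]:
        if self.sweep_percents is None:
            return None
        return W34_BASELINE * self.sweep_percents / 100.0


def _parse_sweep(spec: Dict) -> np.ndarray:
    unknown = set(spec) - _SWEEP_KEYS
    if unknown:
        raise ValueError(f"unknown sweep keys: {sorted(unknown)}")
    if "percents" in spec:
        arr = np.asarray(spec["percents"], dtype=float)
    else:
        lo = float(spec.get("lo_percent", 30.0))
        hi = float(spec.get("hi_percent", 160.0))
        step = float(spec.get("step_percent", 1.0))
        arr = np.arange(lo, hi + 0.5 * step, step)
    if arr.ndim != 1 or np.any(np.diff(arr) <= 0):
        raise ValueError("sweep percents must be strictly increasing")
    return arr


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration.

    Layout::

        profile: paper_defaults      # optional; printed parameter values
        task: bifurcation            # optional pipeline name
        parameters: {w34: 0.36, d_max: 3.5, ...}
        simulation: {dt: 0.001, n_steps: 120000, ...}
        sweep: {lo_percent: 30, hi_percent: 160, step_percent: 1}

    Unknown keys are rejected.  ``d_max`` is not a published constant: a
    config that sets any model parameter must either set ``d_max`` or state
    ``acknowledge_d_max_default: true`` to accept this package's
    reconstruction (default 3.5).
    """
    path = Path(path)
    text = path.read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    profile = raw.get("profile")
    if profile not in (None, "paper_defaults"):
        raise ValueError(f"unknown profile {profile!r}")

    pdict = dict(raw.get("parameters") or {})
    unknown = set(pdict) - _PARAM_KEYS
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    if pdict and "d_max" not in pdict and profile is None \
            and not raw.get("acknowledge_d_max_default", False):
        raise ValueError(
            "config sets model parameters but omits d_max, which is not a "
            "published constant (this package reconstructs it as 3.5). Set "
            "d_max explicitly, or set 'acknowledge_d_max_default: true', or "
            "use 'profile: paper_defaults'.")
    params = paper_defaults(**{k: float(v) for k, v in pdict.items()})

    sdict = dict(raw.get("simulation") or {})
    unknown = set(sdict) - _SIM_KEYS
    if unknown:
        raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
    settings = SimulationSettings(**sdict)

    sweep = raw.get("sweep")
    sweep_percents = _parse_sweep(dict(sweep)) if sweep is not None else None

    return RunConfig(params=params, settings=settings,
                     sweep_percents=sweep_percents, task=raw.get("task"))


def save_config(config: RunConfig, path) -> None:
    """Serialize a RunConfig so that ``load_config(save_config(c)) == c``."""
    path = Path(path)
    doc = {
        "parameters": config.params.to_dict(),
        "simulation": {
            "dt": config.settings.dt,
            "n_steps": config.settings.n_steps,
            "n_realizations": config.settings.n_realizations,
            "seed": config.settings.seed,
            **({"record_every": config.settings.record_every}
               if config.settings.record_every is not None else {}),
        },
    }
    if config.sweep_percents is not None:
        doc["sweep"] = {"percents": [float(v) for v in config.sweep_percents]}
    if config.task is not None:
        doc["task"] = config.task
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
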