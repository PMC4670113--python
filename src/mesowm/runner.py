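"""Experiment pipelines, persistence and the reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, save_config
from .equilibrium import bifurcation_scan, find_fixed_points
from .landscape import estimate_distribution, potential, robustness_profile
from .params import W34_BASELINE
from .simulate import simulate_ensemble
from .snr import snr_profile

__all__ = ["RunManifest", "run_experiment", "TASKS"]

log = logging.getLogger(__name__)

#: Recorded model caveats carried into every manifest.
MODEL_CAVEATS = [
    "d_max is not a published constant; the bundled default 3.5 is a "
    "reconstruction, and landmark locations depend on it.",
    "the interneuron time-constant modulation tau2 = tau2*(0.24 z + 0.26) is "
    "published in an undefined variable z; this package identifies z with "
    "the D1 activation level d, under which tau2 increases with d even "
    "though the surrounding text describes a decrease.",
]


@dataclass
class RunManifest:
    """Everything needed to re-run a pipeline bit-identically."""

    task: str
    created: str
    software_version: str
    parameters: Dict[str, float]
    simulation: Dict
    sweep_percents: Optional[List[float]]
    seed: int
    files: Dict[str, str] = field(default_factory=dict)  # name -> sha256
    caveats: List[str] = field(default_factory=lambda: list(MODEL_CAVEATS))

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    df.to_csv(path, index=False)
    manifest.files[path.name] = _sha256(path)


def _write_json(obj, path: Path, manifest: RunManifest) -> None:
    path.write_text(json.dumps(obj, indent=2))
    manifest.files[path.name] = _sha256(path)


def _task_bifurcation(config: RunConfig, out: Path, manifest: RunManifest) -> None:
    grid = config.sweep_w34()
    diagram = bifurcation_scan(grid, config.params)
    _write(diagram.to_frame(), out / "bifurcation.csv", manifest)
    side: Dict = {"zones": {f"{100 * w / W34_BASELINE:.4g}%": z
                            for w, z in (diagram.zones or {}).items()}}
    if diagram.landmarks is not None:
        lm = diagram.landmarks
        side["landmarks"] = {
            "P": lm.P, "Q": lm.Q, "R": lm.R,
            "P_percent": 100 * lm.P / W34_BASELINE,
            "Q_percent": 100 * lm.Q / W34_BASELINE,
            "R_percent": 100 * lm.R / W34_BASELINE,
            "d_max": config.params.d_max,
        }
    _write_json(side, out / "landmarks.json", manifest)


def _task_simulate(config: RunConfig, out: Path, manifest: RunManifest) -> None:
    p = config.params
    fps = find_fixed_points(p.w34, p)
    if len(fps) < 3:
        raise ValueError(
            f"w34={p.w34:.5g} is monostable (zone I); the published protocol "
            "starts from the interior unstable fixed point, which does not "
            "exist here")
    res = simulate_ensemble(fps[1].state, p, config.settings)
    try:
        import h5py

        with h5py.File(out / "ensemble.h5", "w") as f:
            ds = f.create_dataset("final_states", data=res.final_states)
            ds.attrs["w34"] = res.w34
            ds.attrs["seed"] = config.settings.seed
            ds.attrs["dt"] = config.settings.dt
            ds.attrs["n_steps"] = config.settings.n_steps
            ds.attrs["init"] = res.init
        manifest.files["ensemble.h5"] = _sha256(out / "ensemble.h5")
    except ImportError:  # pragma: no cover
        pass
    if res.n <= 100_000:
        df = pd.DataFrame(res.final_states, columns=["x1", "x2", "x3", "x4"])
        _write(df, out / "final_states.csv", manifest)


def _task_landscape(config: RunConfig, out: Path, manifest: RunManifest) -> None:
    p = config.params
    fps = find_fixed_points(p.w34, p)
    if len(fps) < 3:
        raise ValueError(f"w34={p.w34:.5g} is monostable (zone I); no "
                         "landscape with two wells exists")
    res = simulate_ensemble(fps[1].state, p, config.settings)
    dist = estimate_distribution(res, axes=("x1",), bins=100)
    land = potential(dist, separatrix_x1=fps[1].x1)
    _write(land.to_frame(), out / "landscape.csv", manifest)
    _write_json({
        "separatrix_x1": land.separatrix_x1,
        "U_low": land.U_low, "U_high": land.U_high,
        "barrier": land.barrier,
        "bin_edges": [float(v) for v in dist.bin_edges[0]],
    }, out / "landscape.json", manifest)


def _task_robustness(config: RunConfig, out: Path, manifest: RunManifest) -> None:
    grid = config.sweep_w34()
    if grid is None:
        raise ValueError("robustness task needs a sweep specification")
    prof = robustness_profile(grid, config.params, config.settings)
    _write(prof.table, out / "robustness_profile.csv", manifest)
    _write_json({"w34_star": prof.w34_star,
                 "w34_star_percent": 100 * prof.w34_star / W34_BASELINE,
                 "bin_edges": [float(v) for v in prof.bin_edges]},
                out / "robustness.json", manifest)


def _task_snr(config: RunConfig, out: Path, manifest: RunManifest) -> None:
    grid = config.sweep_w34()
    if grid is None:
        raise ValueError("snr task needs a sweep specification")
    prof = snr_profile(grid, config.params, config.settings)
    _write(prof.table, out / "snr_profile.csv", manifest)
    _write_json({"peak_w34_x1": prof.peak_w34("x1"),
                 "peak_w34_x3": prof.peak_w34("x3")},
                out / "snr.json", manifest)


TASKS = {
    "bifurcation": _task_bifurcation,
    "simulate": _task_simulate,
    "landscape": _task_landscape,
    "robustness": _task_robustness,
    "snr": _task_snr,
}


def run_experiment(config: RunConfig, out_dir, task: Optional[str] = None) -> RunManifest:
    """Execute one named pipeline and write its outputs plus a manifest.

    The manifest records parameters, settings, sweep, seed, software version
    and the sha256 of every produced file; identical config + seed produce
    identical checksums.
    """
    task = task or config.task
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; choose from {sorted(TASKS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        task=task,
        created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        software_version=__version__,
        parameters=config.params.to_dict(),
        simulation={"dt": config.settings.dt,
                    "n_steps": config.settings.n_steps,
                    "n_realizations": config.settings.n_realizations,
                    "record_every": config.settings.record_every},
        sweep_percents=None if config.sweep_percents is None
        else [float(v) for v in config.sweep_percents],
        seed=config.settings.seed,
    )
    t0 = time.time()
    TASKS[task](config, out, manifest)
    log.info("task %s finished in %.1fs", task, time.time() - t0)
    save_config(config, out / "config.yaml")
    manifest.files["config.yaml"] = _sha256(out / "config.yaml")
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
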