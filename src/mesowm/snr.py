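"""Signal-to-noise ratio of circuit activity in the working-memory state.

The SNR of a variable is its ensemble mean divided by the standard deviation
of its fluctuations (population convention).  Samples are assigned to the
spontaneous (lower) or sustained-firing (upper) basin by the x1 coordinate
of the interior unstable fixed point; conditional statistics are computed
per basin and unconditional statistics over the whole ensemble.

The profile over dopamine releasability is computed with the delay-period
protocol: every realization starts in the sustained-firing (upper) fixed
point and runs for the delay horizon, so the unconditional mean measures how
well the working-memory state survives the delay — at low releasability it
collapses toward the spontaneous state and the SNR drops steeply, producing
the inverted-U profile with its maximum near 100% releasability.  The
unstable-point initialization used for the landscape analyses is available
via ``init="unstable"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .equilibrium import FixedPoint, find_fixed_points
from .params import ModelParameters, W34_BASELINE
from .simulate import EnsembleResult, SimulationSettings, simulate_ensemble

__all__ = ["BasinLabeledSamples", "SNRProfile", "assign_basins",
           "conditional_snr", "snr_profile"]

log = logging.getLogger(__name__)

_VARS = {"x1": 0, "x2": 1, "x3": 2, "x4": 3}

#: Basins with fewer samples than this yield flagged (NaN) statistics.
MIN_BASIN_COUNT = 100


@dataclass
class BasinLabeledSamples:
    """Ensemble terminal states with lower/upper basin labels."""

    samples: np.ndarray        # (N, 4)
    labels: np.ndarray         # (N,) bool, True = upper basin
    separatrix_x1: float

    @property
    def occupancy_upper(self) -> float:
        return float(self.labels.mean())

    @property
    def occupancy_lower(self) -> float:
        return 1.0 - self.occupancy_upper

    def basin(self, which: str) -> np.ndarray:
        if which == "upper":
            return self.samples[self.labels]
        if which == "lower":
            return self.samples[~self.labels]
        raise ValueError("basin must be 'lower' or 'upper'")


def assign_basins(result: EnsembleResult,
                  fixed_points: Sequence[FixedPoint]) -> BasinLabeledSamples:
    """Label every sample by the x1 separatrix of the unstable fixed point.

    ``fixed_points`` must contain the bistable triple (lower, unstable,
    upper); monostable input is refused.  Ties (x1 exactly at the
    separatrix) go to the lower basin.
    """
    if len(fixed_points) < 3:
        raise ValueError("basin assignment requires a bistable fixed-point "
                         "structure (no interior unstable point found)")
    sep = fixed_points[1].x1
    labels = result.final_states[:, 0] > sep
    return BasinLabeledSamples(samples=result.final_states, labels=labels,
                               separatrix_x1=sep)


def _snr(values: np.ndarray, variance_ratio: bool = False) -> float:
    mean = float(values.mean())
    var = float(values.var())  # population convention
    if var == 0.0:
        return np.nan
    return mean / var if variance_ratio else mean / np.sqrt(var)


def conditional_snr(labeled: BasinLabeledSamples, variable: str = "x1",
                    basin: str = "upper", variance_ratio: bool = False,
                    min_count: int = MIN_BASIN_COUNT) -> float:
    """Mean over standard deviation of ``variable`` within ``basin``.

    Returns NaN (undefined-SNR flag) when the basin holds fewer than
    ``min_count`` samples or the conditional variance is zero.  With
    ``variance_ratio`` the mean/variance rendering is used instead of
    mean/standard-deviation.
    """
    sub = labeled.basin(basin)
    if sub.shape[0] < min_count:
        return np.nan
    return _snr(sub[:, _VARS[variable]], variance_ratio)


@dataclass
class SNRProfile:
    """Conditional and unconditional SNR statistics across a W34 grid."""

    table: pd.DataFrame
    settings: SimulationSettings
    params: ModelParameters
    init: str

    def variable(self, variable: str, basin: str = "upper") -> pd.DataFrame:
        t = self.table
        return t[(t.variable == variable) & (t.basin == basin)].reset_index(drop=True)

    def peak_w34(self, variable: str = "x1", basin: str = "unconditional") -> float:
        sub = self.variable(variable, basin)
        return float(sub.w34.iloc[int(np.nanargmax(sub.snr.values))])


def snr_profile(
    w34_grid: Sequence[float],
    params: ModelParameters,
    settings: SimulationSettings,
    init: str = "upper",
    variables: Sequence[str] = ("x1", "x3"),
    variance_ratio: bool = False,
) -> SNRProfile:
    """SNR statistics of ``variables`` across a bistable W34 grid.

    For each grid point: fixed points -> ensemble from the chosen initial
    state (``"upper"``: delay-period protocol, the default; ``"unstable"``:
    the landscape protocol) -> basin labels -> conditional and unconditional
    moments.  Rows with insufficient basin occupancy carry NaN statistics
    and ``flagged=True``.  The deterministic upper-branch value is attached
    as the signal reference.
    """
    if init not in ("upper", "unstable"):
        raise ValueError("init must be 'upper' or 'unstable'")
    rows = []
    for w34 in np.asarray(w34_grid, dtype=float):
        p = params.with_w34(w34)
        fps = find_fixed_points(w34, p)
        if len(fps) < 3:
            raise ValueError(
                f"w34={w34:.5g} is monostable; the SNR profile is defined on "
                "the bistable range only")
        x0 = fps[-1].state if init == "upper" else fps[1].state
        log.info("snr: w34=%.5g (%.1f%%)", w34, 100 * w34 / W34_BASELINE)
        res = simulate_ensemble(x0, p, settings)
        labeled = assign_basins(res, fps)
        for var in variables:
            col = res.final_states[:, _VARS[var]]
            det = float(fps[-1].state[_VARS[var]])
            for basin in ("lower", "upper"):
                sub = labeled.basin(basin)[:, _VARS[var]]
                n = sub.shape[0]
                ok = n >= MIN_BASIN_COUNT
                rows.append({
                    "w34": w34, "percent": 100 * w34 / W34_BASELINE,
                    "variable": var, "basin": basin,
                    "mean": float(sub.mean()) if ok else np.nan,
                    "sd": float(sub.std()) if ok else np.nan,
                    "snr": _snr(sub, variance_ratio) if ok else np.nan,
                    "n": n, "occupancy": n / res.n,
                    "deterministic_signal": det,
                    "flagged": not ok,
                })
            rows.append({
                "w34": w34, "percent": 100 * w34 / W34_BASELINE,
                "variable": var, "basin": "unconditional",
                "mean": float(col.mean()), "sd": float(col.std()),
                "snr": _snr(col, variance_ratio),
                "n": res.n, "occupancy": 1.0,
                "deterministic_signal": det,
                "flagged": False,
            })
    return SNRProfile(table=pd.DataFrame(rows), settings=settings,
                      params=params, init=init)
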