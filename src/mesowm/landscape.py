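"""Steady-state distributions, potential landscapes and robustness profiles.

The ensemble of terminal states defines a sampled probability distribution
P_st over chosen marginals of the state space; the (dimensionless) potential
is ``U = -ln P_st`` on occupied bins.  Wells are the potential minima of the
two basins split at the x1 coordinate of the interior unstable fixed point
(the operational separatrix), and the barrier is the potential maximum on
the 1-D x1 marginal between the two well bins.  All reported robustness
comparisons are potential differences, so the additive normalization
constant is irrelevant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .equilibrium import FixedPoint, find_fixed_points
from .model import d1_activation
from .params import ModelParameters, W34_BASELINE
from .simulate import EnsembleResult, SimulationSettings, simulate_ensemble

__all__ = [
    "SteadyStateDistribution",
    "PotentialLandscape",
    "RobustnessProfile",
    "estimate_distribution",
    "potential",
    "robustness_profile",
]

log = logging.getLogger(__name__)

_AXIS_COLUMNS = {"x1": 0, "x2": 1, "x3": 2, "x4": 3}


@dataclass
class SteadyStateDistribution:
    """Normalized histogram of ensemble terminal states on a marginal."""

    axes: Tuple[str, ...]
    bin_edges: List[np.ndarray]
    probabilities: np.ndarray
    sample_count: int

    @property
    def bin_centers(self) -> List[np.ndarray]:
        return [0.5 * (e[1:] + e[:-1]) for e in self.bin_edges]

    def rescaled(self, c: float) -> "SteadyStateDistribution":
        """Multiply probabilities by ``c`` (gauge test helper; unnormalized)."""
        out = SteadyStateDistribution(self.axes, self.bin_edges,
                                      self.probabilities * c, self.sample_count)
        return out


@dataclass
class Well:
    """Location and potential of one basin's minimum."""

    index: Tuple[int, ...]
    center: Tuple[float, ...]
    potential: float

    @property
    def x1(self) -> float:
        return self.center[0]


@dataclass
class PotentialLandscape:
    """Negative-log-probability landscape with well and barrier statistics."""

    distribution: SteadyStateDistribution
    potential: np.ndarray                 # -ln p, +inf on empty bins
    separatrix_x1: float
    well_low: Optional[Well]
    well_high: Optional[Well]
    barrier: Optional[float]              # max U between wells, x1 marginal

    @property
    def U_low(self) -> float:
        return np.nan if self.well_low is None else self.well_low.potential

    @property
    def U_high(self) -> float:
        return np.nan if self.well_high is None else self.well_high.potential

    def to_frame(self) -> pd.DataFrame:
        """Tidy table (bin centers..., probability, potential), occupied bins."""
        centers = self.distribution.bin_centers
        mesh = np.meshgrid(*centers, indexing="ij")
        p = self.distribution.probabilities
        occ = p > 0
        data = {ax: m[occ] for ax, m in zip(self.distribution.axes, mesh)}
        data["probability"] = p[occ]
        data["potential"] = self.potential[occ]
        return pd.DataFrame(data)


def estimate_distribution(
    result: EnsembleResult,
    axes: Sequence[str] = ("x1",),
    bins: Union[int, Sequence[int]] = 100,
    bin_range: Optional[Sequence[Tuple[float, float]]] = None,
    bin_edges: Optional[Sequence[np.ndarray]] = None,
) -> SteadyStateDistribution:
    """Normalized histogram of terminal states on the chosen marginal.

    ``axes`` is an ordered subset of {x1, x2, x3, x4, d}; the D1 level ``d``
    is computed from x4.  Pass explicit ``bin_edges`` to make landscapes
    comparable across runs.
    """
    axes = tuple(axes)
    cols = []
    for ax in axes:
        if ax == "d":
            cols.append(result.d_values())
        elif ax in _AXIS_COLUMNS:
            cols.append(result.final_states[:, _AXIS_COLUMNS[ax]])
        else:
            raise ValueError(f"unknown axis {ax!r}")
    sample = np.column_stack(cols)
    if sample.shape[0] == 0:
        raise ValueError("empty ensemble")
    if bin_edges is not None:
        hist, edges = np.histogramdd(sample, bins=list(bin_edges))
    else:
        hist, edges = np.histogramdd(sample, bins=bins, range=bin_range)
    total = hist.sum()
    if total == 0:
        raise ValueError("no samples fell inside the binning range")
    p = hist / total
    if np.max(p) == 1.0 and p.size > 1:
        warnings.warn("all samples fell in a single bin; binning too coarse "
                      "for landscape work", stacklevel=2)
    return SteadyStateDistribution(axes=axes, bin_edges=[np.asarray(e) for e in edges],
                                   probabilities=p, sample_count=int(total))


def potential(dist: SteadyStateDistribution, separatrix_x1: float,
              pseudo_count: bool = False) -> PotentialLandscape:
    """Potential landscape ``U = -ln p`` with wells split at the separatrix.

    Empty bins carry no potential value (they are excluded, not infinite
    wells); with ``pseudo_count`` every bin receives an extra 1/N sample for
    plotting continuity.  The first axis must be x1 so that basins can be
    assigned; wells are the minima of U on each side, and the barrier is the
    maximum of the 1-D x1-marginal potential between the two well positions.
    A basin with zero occupancy is reported as an absent well (None).
    """
    if dist.axes[0] != "x1":
        raise ValueError("potential analysis requires x1 as the first axis")
    p = dist.probabilities.astype(float)
    if pseudo_count:
        p = p + 1.0 / max(dist.sample_count, 1)
        p = p / p.sum()
    with np.errstate(divide="ignore"):
        U = np.where(p > 0, -np.log(np.where(p > 0, p, 1.0)), np.inf)

    centers_x1 = dist.bin_centers[0]

    def _well(mask_side) -> Optional[Well]:
        occ = (p > 0) & mask_side[(...,) + (np.newaxis,) * (p.ndim - 1)] \
            if p.ndim > 1 else (p > 0) & mask_side
        if not np.any(occ):
            return None
        Uside = np.where(occ, U, np.inf)
        idx = np.unravel_index(int(np.argmin(Uside)), U.shape)
        center = tuple(float(c[i]) for c, i in zip(dist.bin_centers, idx))
        return Well(index=idx, center=center, potential=float(U[idx]))

    low = _well(centers_x1 < separatrix_x1)
    high = _well(centers_x1 > separatrix_x1)

    barrier = None
    if low is not None and high is not None:
        # marginal barrier: collapse onto x1, max potential between the wells
        p1 = p.reshape(p.shape[0], -1).sum(axis=1)
        with np.errstate(divide="ignore"):
            U1 = np.where(p1 > 0, -np.log(np.where(p1 > 0, p1, 1.0)), -np.inf)
        i0, i1 = sorted((low.index[0], high.index[0]))
        between = U1[i0:i1 + 1]
        finite = between[np.isfinite(between)]
        if finite.size:
            barrier = float(np.max(finite))
    return PotentialLandscape(distribution=dist, potential=U,
                              separatrix_x1=float(separatrix_x1),
                              well_low=low, well_high=high, barrier=barrier)


@dataclass
class RobustnessProfile:
    """Well potentials of both states across a W34 grid."""

    table: pd.DataFrame            # w34, percent, U_low, U_high, barrier, flags
    w34_star: float                # argmin of the smoothed U_high profile
    w34_star_grid: float           # raw grid argmin of U_high
    bin_edges: np.ndarray          # shared x1 edges
    settings: SimulationSettings
    params: ModelParameters

    @property
    def U_high(self) -> np.ndarray:
        return self.table["U_high"].to_numpy()

    @property
    def U_low(self) -> np.ndarray:
        return self.table["U_low"].to_numpy()


def _smooth_argmin(w: np.ndarray, u: np.ndarray) -> float:
    """Argmin of a quadratic fit to the sampled potential profile.

    The Monte-Carlo scatter of the well potentials is comparable to the
    curvature of the profile on realistic ensemble sizes, so the minimum is
    read from a smooth fit through the points rather than from the raw
    grid minimum (the figure-style treatment of the profile).  Falls back
    to the grid argmin when the fitted parabola is concave or its vertex
    leaves the scanned range.
    """
    grid_star = float(w[int(np.nanargmin(u))])
    if len(w) < 4:
        return grid_star
    c2, c1, _ = np.polyfit(w, u, 2)
    if c2 <= 0:
        return grid_star
    vertex = -c1 / (2 * c2)
    if not (w.min() <= vertex <= w.max()):
        return grid_star
    return float(vertex)


def robustness_profile(
    w34_grid: Sequence[float],
    params: ModelParameters,
    settings: SimulationSettings,
    n_bins: int = 100,
    x1_range: Tuple[float, float] = (-1.0, 3.5),
    pipeline_hook=None,
) -> RobustnessProfile:
    """Trace U_high, U_low and the barrier over a bistable W34 grid.

    For each grid value: locate the fixed points (monostable values are
    refused — the published analysis excludes zone I), run the ensemble from
    the interior unstable point, histogram the x1 marginal on shared bin
    edges, and read off the well potentials.  ``w34_star`` is the grid argmin
    of U_high, the most robust sustained-firing configuration.
    """
    edges = np.linspace(x1_range[0], x1_range[1], n_bins + 1)
    rows = []
    for w34 in np.asarray(w34_grid, dtype=float):
        p = params.with_w34(w34)
        fps = find_fixed_points(w34, p)
        if len(fps) < 3:
            raise ValueError(
                f"w34={w34:.5g} ({100 * w34 / W34_BASELINE:.1f}%) is outside "
                "the bistable range; the robustness profile is defined on "
                "zones II-IV only")
        unstable = fps[1]
        log.info("robustness: w34=%.5g (%.1f%%)", w34, 100 * w34 / W34_BASELINE)
        res = simulate_ensemble(unstable.state, p, settings)
        if pipeline_hook is not None:
            pipeline_hook(w34, res)
        dist = estimate_distribution(res, axes=("x1",), bin_edges=[edges])
        land = potential(dist, separatrix_x1=unstable.x1)
        flagged = land.well_high is None or land.well_low is None
        if flagged:
            log.warning("missing well occupancy at w34=%.5g", w34)
        rows.append({
            "w34": w34, "percent": 100 * w34 / W34_BASELINE,
            "U_low": land.U_low, "U_high": land.U_high,
            "barrier": np.nan if land.barrier is None else land.barrier,
            "occupancy_high": float(np.mean(res.final_states[:, 0] > unstable.x1)),
            "separatrix_x1": unstable.x1,
            "flagged": flagged,
        })
    table = pd.DataFrame(rows)
    valid = table[~table.flagged]
    if valid.empty or valid.U_high.isna().all():
        raise ValueError("no grid point produced an occupied upper well")
    w34_star_grid = float(valid.w34.iloc[int(np.nanargmin(valid.U_high.values))])
    w34_star = _smooth_argmin(valid.w34.to_numpy(), valid.U_high.to_numpy())
    return RobustnessProfile(table=table, w34_star=w34_star,
                             w34_star_grid=w34_star_grid, bin_edges=edges,
                             settings=settings, params=params)
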