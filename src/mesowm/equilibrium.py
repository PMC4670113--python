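"""Fixed points, bifurcation diagram and landmarks of the circuit.

At equilibrium the last three equations back-substitute into the first:

    x3* = tau3 W13 g(x1),   x4* = tau4 W34 g(x3*),   d = d_max g(x4*),
    x2* = tau2(d) W12(d) g(x1),

reducing the four-dimensional condition ``f(x*) = 0`` to one scalar equation
``f1(x1) = 0`` in the pyramidal activity.  Roots are bracketed on a uniform
grid and polished with Brent's method; stability comes from the analytic
Jacobian (one-sided at the origin).

Sweeping the dopamine releasability W34 yields the bifurcation diagram with
a saddle-node fold P where bistability appears, and landmarks Q and R where
the upper-branch pyramidal and interneuron activities peak.  Zones:
I = [low, P), II = [P, Q), III = [Q, R), IV = [R, high].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import force, jacobian, origin_jacobian, saturation, modulate, d1_activation
from .params import ModelParameters, W34_BASELINE

__all__ = [
    "FixedPoint",
    "BifurcationDiagram",
    "Landmarks",
    "self_consistency_residual",
    "back_substitute",
    "find_fixed_points",
    "bifurcation_scan",
    "locate_landmarks",
    "default_w34_grid",
]

#: Eigenvalue real parts closer to zero than this are treated as marginal.
EIGENVALUE_TOL = 1e-8


@dataclass(frozen=True)
class FixedPoint:
    """An equilibrium of the deterministic circuit."""

    state: np.ndarray            # (4,) [x1, x2, x3, x4]
    d: float                     # D1 activation at the equilibrium
    eigenvalues: np.ndarray      # (4,) complex
    stability: str               # "stable" | "unstable" | "non-classifiable"
    residual_norm: float         # max-norm of force at the state

    @property
    def x1(self) -> float:
        return float(self.state[0])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        x = ", ".join(f"{v:.4g}" for v in self.state)
        return f"FixedPoint([{x}], d={self.d:.4g}, {self.stability})"


@dataclass(frozen=True)
class Landmarks:
    """W34 locations of the fold P and the branch maxima Q (x1) and R (x2)."""

    P: float
    Q: float
    R: float

    def zone(self, w34: float) -> str:
        if w34 < self.P:
            return "I"
        if w34 < self.Q:
            return "II"
        if w34 < self.R:
            return "III"
        return "IV"


@dataclass
class BifurcationDiagram:
    """Fixed points across a W34 sweep, with landmarks and zone labels."""

    w34_grid: np.ndarray
    points: List[List[FixedPoint]]
    params: ModelParameters
    landmarks: Optional[Landmarks] = None
    zones: Optional[Dict[float, str]] = None
    fold_warning: bool = False

    def n_fixed_points(self) -> np.ndarray:
        return np.array([len(p) for p in self.points])

    def bistable_mask(self) -> np.ndarray:
        return self.n_fixed_points() >= 3

    def branch(self, which: str) -> pd.DataFrame:
        """Tidy frame of one branch: 'lower', 'unstable' or 'upper'.

        The lower branch is the origin; in the bistable range the unstable
        branch is the interior saddle and the upper branch the sustained-
        firing state (largest x1).
        """
        rows = []
        for w34, fps in zip(self.w34_grid, self.points):
            fp = None
            if which == "lower":
                fp = fps[0]
            elif which == "unstable" and len(fps) >= 3:
                fp = fps[1]
            elif which == "upper" and len(fps) >= 3:
                fp = fps[-1]
            if fp is not None:
                rows.append({"w34": w34, "percent": 100 * w34 / W34_BASELINE,
                             "x1": fp.state[0], "x2": fp.state[1],
                             "x3": fp.state[2], "x4": fp.state[3],
                             "d": fp.d, "stability": fp.stability})
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Full tidy table: one row per (w34, fixed point)."""
        rows = []
        for w34, fps in zip(self.w34_grid, self.points):
            for branch_id, fp in enumerate(fps):
                rows.append({
                    "w34": w34,
                    "percent": 100 * w34 / W34_BASELINE,
                    "branch_id": branch_id,
                    "x1": fp.state[0], "x2": fp.state[1],
                    "x3": fp.state[2], "x4": fp.state[3],
                    "d": fp.d, "stability": fp.stability,
                    "eigen_real_max": float(np.max(fp.eigenvalues.real)),
                })
        return pd.DataFrame(rows)


def self_consistency_residual(x1, w34: float, params: ModelParameters):
    """Scalar equilibrium residual ``f1`` on the back-substituted state.

    Vectorized over ``x1 >= 0``.  A root of this function, back-substituted,
    is a fixed point of the full four-dimensional system.
    """
    x1 = np.asarray(x1, dtype=float)
    a = params.a
    g1 = np.tanh(a * np.maximum(x1, 0.0))
    x3 = params.tau3 * params.w13 * g1
    x4 = params.tau4 * w34 * np.tanh(a * x3)
    d = params.d_max * np.tanh(a * x4)
    m = 0.12 * d + 0.68
    tau2_d = params.tau2_star * (0.24 * d + 0.26)
    x2 = tau2_d * params.w12_star * m * g1
    r = -x1 / params.tau1 + params.w11_star * m * g1 \
        - params.w21 * np.tanh(a * x2)
    return r if r.ndim else float(r)


def back_substitute(x1: float, w34: float, params: ModelParameters) -> np.ndarray:
    """Full state on the equilibrium manifold parametrized by x1."""
    a = params.a
    g1 = float(np.tanh(a * max(x1, 0.0)))
    x3 = params.tau3 * params.w13 * g1
    x4 = params.tau4 * w34 * float(np.tanh(a * x3))
    d = params.d_max * float(np.tanh(a * x4))
    x2 = params.tau2_star * (0.24 * d + 0.26) * params.w12_star * (0.12 * d + 0.68) * g1
    return np.array([x1, x2, x3, x4])


def _classify(eigvals: np.ndarray) -> str:
    re = eigvals.real
    if np.any(np.abs(re) < EIGENVALUE_TOL):
        return "non-classifiable"
    return "stable" if np.all(re < 0) else "unstable"


def _make_fixed_point(x1: float, w34: float, params: ModelParameters) -> FixedPoint:
    p = params.with_w34(w34)
    state = back_substitute(x1, w34, params)
    res = float(np.max(np.abs(force(state, p))))
    if x1 <= 0 or np.any(state <= 0):
        eig = np.linalg.eigvals(origin_jacobian(p))
    else:
        eig = np.linalg.eigvals(jacobian(state, p))
    d = float(d1_activation(state[3], p))
    return FixedPoint(state=state, d=d, eigenvalues=eig,
                      stability=_classify(eig), residual_norm=res)


def find_fixed_points(
    w34: float,
    params: ModelParameters,
    x1_max: float = 30.0,
    n_grid: int = 2000,
    xtol: float = 1e-12,
) -> List[FixedPoint]:
    """All fixed points at releasability ``w34``, sorted by ascending x1.

    The origin is always included.  Interior roots of the scalar residual are
    isolated by sign changes on a uniform grid over ``(0, x1_max]`` and
    polished by Brent's method.  A warning flag is attached via
    ``warnings.warn`` if two roots fall within one grid cell of each other
    (possible missed root near a fold).
    """
    xs = np.linspace(1e-9, x1_max, n_grid)
    r = self_consistency_residual(xs, w34, params)
    sign = np.sign(r)
    idx = np.where(sign[:-1] * sign[1:] < 0)[0]
    roots = [0.0]
    for i in idx:
        root = brentq(self_consistency_residual, xs[i], xs[i + 1],
                      args=(w34, params), xtol=xtol)
        roots.append(root)
    # exact-zero grid hits (vanishingly unlikely off the origin)
    for i in np.where(r == 0.0)[0]:
        if xs[i] > 1e-8:
            roots.append(float(xs[i]))
    roots = sorted(set(roots))
    if len(roots) >= 2:
        gaps = np.diff(roots)
        if np.any(gaps[1:] < (x1_max / n_grid)):
            warnings.warn(
                f"two fixed-point roots closer than the grid resolution at "
                f"w34={w34:.5g}; a root near a fold may have been missed",
                stacklevel=2,
            )
    return [_make_fixed_point(x, w34, params) for x in roots]


def default_w34_grid(lo_percent: float = 30.0, hi_percent: float = 160.0,
                     step_percent: float = 1.0) -> np.ndarray:
    """Default W34 sweep: 30%-160% of the baseline 0.36 in 1% steps."""
    pct = np.arange(lo_percent, hi_percent + 0.5 * step_percent, step_percent)
    return W34_BASELINE * pct / 100.0


def bifurcation_scan(
    w34_grid: Optional[Sequence[float]] = None,
    params: Optional[ModelParameters] = None,
    refine_fold: bool = True,
    **find_kwargs,
) -> BifurcationDiagram:
    """Fixed points at each grid value, with landmarks and zones.

    The fold P is refined by bisection on the 1 <-> 3 root-count transition
    to a W34 tolerance of 1e-5.
    """
    params = params or ModelParameters()
    grid = np.asarray(w34_grid if w34_grid is not None else default_w34_grid(),
                      dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("w34_grid must be strictly increasing")
    points = [find_fixed_points(w, params, **find_kwargs) for w in grid]
    diagram = BifurcationDiagram(w34_grid=grid, points=points, params=params)
    try:
        diagram.landmarks = locate_landmarks(diagram, refine_fold=refine_fold,
                                             **find_kwargs)
        diagram.zones = {float(w): diagram.landmarks.zone(w) for w in grid}
    except ValueError:
        diagram.fold_warning = True
    return diagram


def _refine_fold(w_lo: float, w_hi: float, params: ModelParameters,
                 tol: float = 1e-5, **find_kwargs) -> float:
    """Bisection on the root count over [w_lo (1 root), w_hi (3 roots)]."""
    while w_hi - w_lo > tol:
        mid = 0.5 * (w_lo + w_hi)
        with warnings.catch_warnings():
            # near the fold the merging root pair legitimately crowds the grid
            warnings.simplefilter("ignore")
            n = len(find_fixed_points(mid, params, **find_kwargs))
        if n >= 3:
            w_hi = mid
        else:
            w_lo = mid
    return 0.5 * (w_lo + w_hi)


def locate_landmarks(diagram: BifurcationDiagram, refine_fold: bool = True,
                     **find_kwargs) -> Landmarks:
    """Locate P (bistability onset), Q (upper-branch x1 max), R (x2 max).

    Raises ``ValueError`` if the scan contains no monostable -> bistable
    transition, or if the ordering P < Q < R is violated.
    """
    n = diagram.n_fixed_points()
    grid = diagram.w34_grid
    trans = np.where((n[:-1] < 3) & (n[1:] >= 3))[0]
    if len(trans) == 0:
        raise ValueError(
            "no monostable->bistable transition inside the scanned W34 range; "
            "extend the grid below the fold to locate landmark P"
        )
    i = trans[0]
    if refine_fold:
        P = _refine_fold(grid[i], grid[i + 1], diagram.params, **find_kwargs)
    else:
        P = float(grid[i + 1])
    upper = diagram.branch("upper")
    if upper.empty:
        raise ValueError("no upper branch found in the scanned range")
    Q = float(upper.w34.iloc[int(np.argmax(upper.x1.values))])
    R = float(upper.w34.iloc[int(np.argmax(upper.x2.values))])
    if not (P < Q < R):
        raise ValueError(
            f"landmark ordering P < Q < R violated (P={P:.5g}, Q={Q:.5g}, "
            f"R={R:.5g}); widen the scan range"
        )
    return Landmarks(P=P, Q=Q, R=R)
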