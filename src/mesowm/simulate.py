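"""Euler-Maruyama ensemble simulation of the Langevin circuit dynamics.

The stochastic model adds independent additive white noise to each circuit
equation, ``dx_i = f_i(x) dt + sigma_i dW_i``, and is integrated with the
fixed-step Euler-Maruyama scheme

    x_i(t + dt) = x_i(t) + f_i(x(t)) dt + sigma_i Z_i sqrt(dt),  Z_i ~ N(0,1).

Ensembles are embarrassingly parallel; each realization runs on its own
deterministically derived RNG sub-stream, so results are bit-reproducible for
a fixed seed regardless of batching.  The published integration protocol is
dt = 0.001 over 120000 steps (120 time units) with N = 1e6 realizations
started at the interior unstable fixed point; analyses in this package scale
N down and may lengthen the horizon (see docs/methods.md).

A linear (Ornstein-Uhlenbeck) reference integrator and the exact stationary
covariance from the Lyapunov equation are provided for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import numba
from scipy.linalg import solve_continuous_lyapunov

from .model import force
from .params import ModelParameters

__all__ = [
    "SimulationSettings",
    "EnsembleResult",
    "em_step",
    "simulate_ensemble",
    "simulate_linear_ensemble",
    "ou_stationary_covariance",
    "burn_in_diagnostic",
]

_GOLDEN = 0x9E3779B1  # odd 32-bit mix constant for per-realization sub-streams


@dataclass(frozen=True)
class SimulationSettings:
    """Integration settings; defaults follow the published protocol."""

    dt: float = 0.001
    n_steps: int = 120_000
    n_realizations: int = 1_000_000
    seed: int = 0
    record_every: Optional[int] = None  # None: keep final states only

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be strictly positive")
        if self.n_steps < 1 or self.n_realizations < 1:
            raise ValueError("n_steps and n_realizations must be >= 1")
        if self.record_every is not None and self.record_every < 1:
            raise ValueError("record_every must be >= 1 when set")

    @property
    def horizon(self) -> float:
        return self.dt * self.n_steps

    def scaled(self, **kw) -> "SimulationSettings":
        return replace(self, **kw)


@dataclass
class EnsembleResult:
    """Terminal states (and optional thinned trajectories) of an ensemble."""

    final_states: np.ndarray          # (N, 4)
    settings: SimulationSettings
    init: np.ndarray                  # (4,)
    w34: float
    params: ModelParameters
    trajectories: Optional[np.ndarray] = None  # (N, n_rec, 4) if recorded
    record_times: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return self.final_states.shape[0]

    def d_values(self) -> np.ndarray:
        """D1 activation of every terminal state (from x4)."""
        from .model import d1_activation

        return d1_activation(self.final_states[:, 3], self.params)


def em_step(state, params: ModelParameters, dt: float, gaussian_draws):
    """One Euler-Maruyama step from ``state`` given 4 standard-normal draws.

    With all noise strengths zero this is exactly the explicit-Euler
    deterministic step.  Vectorized over leading dimensions.
    """
    if dt <= 0:
        raise ValueError("dt must be strictly positive")
    x = np.asarray(state, dtype=float)
    z = np.asarray(gaussian_draws, dtype=float)
    out = x + force(x, params) * dt + params.sigmas * z * np.sqrt(dt)
    if not np.all(np.isfinite(out)):
        bad = np.where(~np.isfinite(np.atleast_2d(out)))[-1]
        raise FloatingPointError(
            f"non-finite state component x{int(bad[0]) + 1} after EM step"
        )
    return out


@numba.njit(cache=True)
def _em_kernel(x0, w34, d_max, sig, dt, n_steps, n_real, seed):
    """Realization-major EM integration of the circuit; final states only."""
    out = np.empty((n_real, 4))
    sq = np.sqrt(dt)
    for r in range(n_real):
        np.random.seed((seed + np.uint32(r) * np.uint32(_GOLDEN)) & np.uint32(0xFFFFFFFF))
        x1, x2, x3, x4 = x0[0], x0[1], x0[2], x0[3]
        for _ in range(n_steps):
            g1 = np.tanh(0.15 * x1) if x1 > 0.0 else 0.0
            g2 = np.tanh(0.15 * x2) if x2 > 0.0 else 0.0
            g3 = np.tanh(0.15 * x3) if x3 > 0.0 else 0.0
            g4 = np.tanh(0.15 * x4) if x4 > 0.0 else 0.0
            d = d_max * g4
            m = 0.12 * d + 0.68
            f1 = -x1 / 20.0 + 0.5588 * m * g1 - 0.339 * g2
            f2 = -x2 / (6.8 * (0.24 * d + 0.26)) + 0.786 * m * g1
            f3 = -x3 / 10.0 + 0.023 * g1
            f4 = -x4 / 800.0 + w34 * g3
            x1 += f1 * dt + sig[0] * np.random.standard_normal() * sq
            x2 += f2 * dt + sig[1] * np.random.standard_normal() * sq
            x3 += f3 * dt + sig[2] * np.random.standard_normal() * sq
            x4 += f4 * dt + sig[3] * np.random.standard_normal() * sq
        out[r, 0] = x1
        out[r, 1] = x2
        out[r, 2] = x3
        out[r, 3] = x4
    return out


@numba.njit(cache=True)
def _em_kernel_generic(x0, w34, d_max, taus, tau2_star, w11s, w12s, w13, w21,
                       a, sig, dt, n_steps, n_real, seed, record_every):
    """EM integration with arbitrary constants and thinned recording."""
    n_rec = n_steps // record_every
    traj = np.empty((n_real, n_rec, 4))
    out = np.empty((n_real, 4))
    sq = np.sqrt(dt)
    for r in range(n_real):
        np.random.seed((seed + np.uint32(r) * np.uint32(_GOLDEN)) & np.uint32(0xFFFFFFFF))
        x1, x2, x3, x4 = x0[0], x0[1], x0[2], x0[3]
        k = 0
        for s in range(n_steps):
            g1 = np.tanh(a * x1) if x1 > 0.0 else 0.0
            g2 = np.tanh(a * x2) if x2 > 0.0 else 0.0
            g3 = np.tanh(a * x3) if x3 > 0.0 else 0.0
            g4 = np.tanh(a * x4) if x4 > 0.0 else 0.0
            d = d_max * g4
            m = 0.12 * d + 0.68
            f1 = -x1 / taus[0] + w11s * m * g1 - w21 * g2
            f2 = -x2 / (tau2_star * (0.24 * d + 0.26)) + w12s * m * g1
            f3 = -x3 / taus[2] + w13 * g1
            f4 = -x4 / taus[3] + w34 * g3
            x1 += f1 * dt + sig[0] * np.random.standard_normal() * sq
            x2 += f2 * dt + sig[1] * np.random.standard_normal() * sq
            x3 += f3 * dt + sig[2] * np.random.standard_normal() * sq
            x4 += f4 * dt + sig[3] * np.random.standard_normal() * sq
            if (s + 1) % record_every == 0 and k < n_rec:
                traj[r, k, 0] = x1
                traj[r, k, 1] = x2
                traj[r, k, 2] = x3
                traj[r, k, 3] = x4
                k += 1
        out[r, 0] = x1
        out[r, 1] = x2
        out[r, 2] = x3
        out[r, 3] = x4
    return out, traj


_DEFAULT_CONSTANTS = ModelParameters().to_dict()


def _is_default_constants(p: ModelParameters) -> bool:
    d = p.to_dict()
    return all(
        d[k] == _DEFAULT_CONSTANTS[k]
        for k in ("tau1", "tau2_star", "tau3", "tau4", "w11_star", "w12_star",
                  "w13", "w21", "a")
    )


def simulate_ensemble(
    init,
    params: ModelParameters,
    settings: SimulationSettings,
    w34: Optional[float] = None,
) -> EnsembleResult:
    """Integrate ``n_realizations`` independent trajectories from ``init``.

    All realizations start exactly at ``init`` (the published protocol uses
    the interior unstable fixed point).  Bit-reproducible for a fixed seed:
    realization ``r`` uses the Mersenne-Twister sub-stream seeded with
    ``(seed + r * 0x9E3779B1) mod 2**32``, independent of batching.
    """
    w34 = float(params.w34 if w34 is None else w34)
    x0 = np.asarray(init, dtype=float)
    if x0.shape != (4,):
        raise ValueError("init must be a 4-vector state")
    sig = params.sigmas
    seed = np.uint32(settings.seed % (2 ** 32))
    if settings.record_every is None and _is_default_constants(params):
        final = _em_kernel(x0, w34, params.d_max, sig, settings.dt,
                           settings.n_steps, settings.n_realizations, seed)
        traj = times = None
    else:
        rec = settings.record_every or settings.n_steps  # record final only
        taus = np.array([params.tau1, 0.0, params.tau3, params.tau4])
        final, traj = _em_kernel_generic(
            x0, w34, params.d_max, taus, params.tau2_star, params.w11_star,
            params.w12_star, params.w13, params.w21, params.a, sig,
            settings.dt, settings.n_steps, settings.n_realizations, seed, rec)
        if settings.record_every is None:
            traj = times = None
        else:
            n_rec = settings.n_steps // rec
            times = settings.dt * rec * np.arange(1, n_rec + 1)
    if not np.all(np.isfinite(final)):
        comp = int(np.where(~np.isfinite(final))[1][0]) + 1
        raise FloatingPointError(f"non-finite terminal state in component x{comp}")
    return EnsembleResult(final_states=final, settings=settings, init=x0,
                          w34=w34, params=params.with_w34(w34),
                          trajectories=traj, record_times=times)


@numba.njit(cache=True)
def _linear_kernel(A, x0, sig, dt, n_steps, n_real, seed):
    n = A.shape[0]
    out = np.empty((n_real, n))
    sq = np.sqrt(dt)
    f = np.empty(n)
    for r in range(n_real):
        np.random.seed((seed + np.uint32(r) * np.uint32(_GOLDEN)) & np.uint32(0xFFFFFFFF))
        x = x0.copy()
        for _ in range(n_steps):
            for i in range(n):
                acc = 0.0
                for j in range(n):
                    acc += A[i, j] * x[j]
                f[i] = acc
            for i in range(n):
                x[i] += f[i] * dt + sig[i] * np.random.standard_normal() * sq
        out[r] = x
    return out


def simulate_linear_ensemble(
    A: np.ndarray,
    init: np.ndarray,
    noise_strengths: np.ndarray,
    settings: SimulationSettings,
) -> np.ndarray:
    """EM ensemble of the linear SDE ``dx = A x dt + diag(sigma) dW``.

    Used to validate the integrator against the exact Ornstein-Uhlenbeck
    stationary law.  Returns terminal states, shape (N, dim).
    """
    A = np.asarray(A, dtype=float)
    x0 = np.asarray(init, dtype=float)
    sig = np.asarray(noise_strengths, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    return _linear_kernel(A, x0, sig, settings.dt, settings.n_steps,
                          settings.n_realizations,
                          np.uint32(settings.seed % (2 ** 32)))


def ou_stationary_covariance(linear_drift: np.ndarray, noise_strengths) -> np.ndarray:
    """Stationary covariance of ``dx = A x dt + diag(sigma) dW``.

    Solves the Lyapunov equation ``A S + S A^T + D = 0`` with
    ``D = diag(sigma_i^2)``.  Requires all eigenvalues of A to have negative
    real part (otherwise no stationary law exists).
    """
    A = np.asarray(linear_drift, dtype=float)
    sig = np.asarray(noise_strengths, dtype=float)
    if np.any(np.linalg.eigvals(A).real >= 0):
        raise ValueError("drift matrix is not stable; no stationary covariance")
    D = np.diag(sig ** 2)
    return solve_continuous_lyapunov(A, -D)


def burn_in_diagnostic(result: EnsembleResult, tail_fraction: float = 0.1) -> np.ndarray:
    """Drift of the ensemble mean of each variable over the final stretch.

    Requires thinned trajectories (``record_every`` set).  Returns the
    absolute change of the ensemble mean over the last ``tail_fraction`` of
    recorded times, per variable — a cheap stationarity check: values well
    above the Monte-Carlo standard error indicate the horizon is too short.
    """
    if result.trajectories is None:
        raise ValueError("burn-in diagnostic needs record_every set during simulation")
    means = result.trajectories.mean(axis=0)  # (n_rec, 4)
    k = max(1, int(round(tail_fraction * means.shape[0])))
    return np.abs(means[-1] - means[-k])
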