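"""Deterministic vector field of the four-variable mesocortical circuit.

State vectors are plain numpy arrays ``[x1, x2, x3, x4]`` (or ``(n, 4)``
batches): pyramidal activity, interneuron activity, midbrain dopaminergic
activity, and DLPFC dopamine content.  The drift is

    f1 = -x1/tau1      + W11(d) g(x1) - W21 g(x2)
    f2 = -x2/tau2(d)   + W12(d) g(x1)
    f3 = -x3/tau3      + W13    g(x1)
    f4 = -x4/tau4      + W34    g(x3)

with the saturation ``g(x) = tanh(a x)`` for x >= 0 and 0 otherwise, and the
D1 activation ``d = d_max g(x4)`` modulating ``W11, W12, tau2`` affinely.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParameters, ModulatedParameters

__all__ = [
    "saturation",
    "saturation_derivative",
    "d1_activation",
    "modulate",
    "force",
    "jacobian",
]


def saturation(x, a: float):
    """Saturating activation ``g(x) = tanh(a x)`` for x >= 0, else 0.

    Monotone non-decreasing, bounded in [0, 1).  ``x`` may be a scalar or an
    array; non-finite input raises.
    """
    if a <= 0:
        raise ValueError("saturation gain a must be strictly positive")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("saturation received non-finite input")
    out = np.tanh(a * np.maximum(x, 0.0))
    return out if out.ndim else float(out)


def saturation_derivative(x, a: float):
    """One-sided derivative of the saturation; ``a`` at 0+ and 0 for x < 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, a * (1.0 - np.tanh(a * np.maximum(x, 0.0)) ** 2), 0.0)
    return out if out.ndim else float(out)


def d1_activation(x4, params: ModelParameters):
    """D1-receptor activation ``d = d_max g(x4)``, in [0, d_max)."""
    return params.d_max * saturation(x4, params.a)


def modulate(d, params: ModelParameters) -> ModulatedParameters:
    """Apply the affine D1 modulation at activation level ``d``.

    ``W11(d) = W11* (0.12 d + 0.68)``, ``W12(d) = W12* (0.12 d + 0.68)`` and
    ``tau2(d) = tau2* (0.24 d + 0.26)``.  The published time-constant rule is
    written in an undefined variable; this package identifies it with ``d``,
    the only free modulatory level in the model (see docs/methods.md).
    """
    d = float(d)
    if d < 0:
        raise ValueError("D1 activation level d must be non-negative")
    m = 0.12 * d + 0.68
    return ModulatedParameters(
        w11_d=params.w11_star * m,
        w12_d=params.w12_star * m,
        tau2_d=params.tau2_star * (0.24 * d + 0.26),
        d=d,
    )


def force(state, params: ModelParameters):
    """Drift vector of the circuit at ``state`` (shape (4,) or (n, 4)).

    The D1 level entering the modulated parameters is computed from the
    instantaneous ``x4``.
    """
    x = np.asarray(state, dtype=float)
    if x.shape[-1] != 4:
        raise ValueError("state must have 4 components")
    if not np.all(np.isfinite(x)):
        raise ValueError("force received non-finite state")
    g = np.tanh(params.a * np.maximum(x, 0.0))
    d = params.d_max * g[..., 3]
    m = 0.12 * d + 0.68
    tau2_d = params.tau2_star * (0.24 * d + 0.26)
    f = np.empty_like(x)
    f[..., 0] = -x[..., 0] / params.tau1 + params.w11_star * m * g[..., 0] \
        - params.w21 * g[..., 1]
    f[..., 1] = -x[..., 1] / tau2_d + params.w12_star * m * g[..., 0]
    f[..., 2] = -x[..., 2] / params.tau3 + params.w13 * g[..., 0]
    f[..., 3] = -x[..., 3] / params.tau4 + params.w34 * g[..., 2]
    return f


def jacobian(state, params: ModelParameters):
    """Analytic 4x4 Jacobian of :func:`force` at an interior state.

    The vector field is non-smooth on the coordinate hyperplanes (the
    saturation has a kink at 0), so every component of ``state`` must be
    strictly positive.  The x4-dependence of rows 1 and 2 enters through the
    chain rule ``d = d_max g(x4)``.
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (4,):
        raise ValueError("jacobian expects a single 4-vector state")
    if np.any(x <= 0):
        raise ValueError(
            "jacobian is undefined at non-smooth points: all state components "
            "must be strictly positive (the saturation has a kink at 0)"
        )
    a = params.a
    g = np.tanh(a * x)
    gp = a * (1.0 - g ** 2)
    d = params.d_max * g[3]
    dd_dx4 = params.d_max * gp[3]
    m = 0.12 * d + 0.68
    dm_dx4 = 0.12 * dd_dx4
    tau2_d = params.tau2_star * (0.24 * d + 0.26)
    dtau2_dx4 = params.tau2_star * 0.24 * dd_dx4

    J = np.zeros((4, 4))
    # f1 = -x1/tau1 + W11* m g1 - W21 g2
    J[0, 0] = -1.0 / params.tau1 + params.w11_star * m * gp[0]
    J[0, 1] = -params.w21 * gp[1]
    J[0, 3] = params.w11_star * dm_dx4 * g[0]
    # f2 = -x2/tau2(d) + W12* m g1
    J[1, 0] = params.w12_star * m * gp[0]
    J[1, 1] = -1.0 / tau2_d
    J[1, 3] = x[1] / tau2_d ** 2 * dtau2_dx4 + params.w12_star * dm_dx4 * g[0]
    # f3 = -x3/tau3 + W13 g1
    J[2, 0] = params.w13 * gp[0]
    J[2, 2] = -1.0 / params.tau3
    # f4 = -x4/tau4 + W34 g3
    J[3, 2] = params.w34 * gp[2]
    J[3, 3] = -1.0 / params.tau4
    return J


def origin_jacobian(params: ModelParameters):
    """One-sided linearization at the origin, using g'(0+) = a and d = 0.

    The origin is an equilibrium for every parameter set; its stability is
    assessed by this one-sided Jacobian since the field is non-smooth there.
    """
    a = params.a
    mod = modulate(0.0, params)
    J = np.zeros((4, 4))
    J[0, 0] = -1.0 / params.tau1 + mod.w11_d * a
    J[0, 1] = -params.w21 * a
    J[1, 0] = mod.w12_d * a
    J[1, 1] = -1.0 / mod.tau2_d
    J[2, 0] = params.w13 * a
    J[2, 2] = -1.0 / params.tau3
    J[3, 2] = params.w34 * a
    J[3, 3] = -1.0 / params.tau4
    return J
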