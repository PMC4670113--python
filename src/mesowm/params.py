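"""Parameter set of the closed-loop mesocortical circuit model.

The model couples four population-level variables: pyramidal activity ``x1``
and GABAergic interneuron activity ``x2`` in the dorsolateral prefrontal
cortex (DLPFC), midbrain dopaminergic activity ``x3``, and the DLPFC dopamine
content ``x4``.  Dopamine acts through D1-receptor activation
``d = d_max * g(x4)``, which modulates the cortical synaptic efficacies and
the interneuron time constant.  All quantities are dimensionless model
activities; time is dimensionless model time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Dict

__all__ = ["ModelParameters", "ModulatedParameters", "paper_defaults", "W34_BASELINE"]

#: Baseline dopamine releasability; sweep positions are quoted as % of this.
W34_BASELINE = 0.36


@dataclass(frozen=True)
class ModelParameters:
    """Constants of the circuit model.

    Attributes
    ----------
    tau1, tau3, tau4 : float
        Relaxation time constants of pyramidal activity, dopaminergic
        activity, and DLPFC dopamine content.
    tau2_star : float
        Basal interneuron time constant; the effective value is
        ``tau2_star * (0.24 d + 0.26)``.
    w11_star, w12_star : float
        Basal recurrent-excitation and pyramidal-to-interneuron efficacies;
        effective values scale with ``0.12 d + 0.68``.
    w13 : float
        Corticomesencephalic (DLPFC -> midbrain) glutamatergic efficacy.
    w21 : float
        Interneuron -> pyramidal inhibitory efficacy.
    w34 : float
        Dopamine releasability, the bifurcation parameter.
    a : float
        Gain of the saturation nonlinearity ``g(x) = tanh(a x)`` for x >= 0.
    d_max : float
        Ceiling of D1-receptor activation.  Not a published constant: the
        default 3.5 is a reconstruction chosen so that the landmark points of
        the bifurcation diagram bracket 100% releasability (see docs).
    sigma1..sigma4 : float
        Additive noise strengths of the four Langevin equations.
    """

    tau1: float = 20.0
    tau2_star: float = 6.8
    tau3: float = 10.0
    tau4: float = 800.0
    w11_star: float = 0.5588
    w12_star: float = 0.786
    w13: float = 0.023
    w21: float = 0.339
    w34: float = W34_BASELINE
    a: float = 0.15
    d_max: float = 3.5
    sigma1: float = 0.05
    sigma2: float = 0.01
    sigma3: float = 0.001
    sigma4: float = 0.05

    def __post_init__(self) -> None:
        for name in ("tau1", "tau2_star", "tau3", "tau4", "a", "d_max"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("w11_star", "w12_star", "w13", "w21", "w34",
                     "sigma1", "sigma2", "sigma3", "sigma4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def sigmas(self):
        import numpy as np

        return np.array([self.sigma1, self.sigma2, self.sigma3, self.sigma4])

    def with_w34(self, w34: float) -> "ModelParameters":
        """Copy of the parameter set at a different dopamine releasability."""
        return replace(self, w34=float(w34))

    def with_w34_percent(self, percent: float) -> "ModelParameters":
        """Copy at ``percent`` % of the baseline releasability 0.36."""
        return self.with_w34(W34_BASELINE * percent / 100.0)

    @property
    def w34_percent(self) -> float:
        return 100.0 * self.w34 / W34_BASELINE

    def to_dict(self) -> Dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: Dict[str, float]) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


@dataclass(frozen=True)
class ModulatedParameters:
    """D1-modulated efficacies and interneuron time constant at level ``d``."""

    w11_d: float
    w12_d: float
    tau2_d: float
    d: float


def paper_defaults(**overrides) -> ModelParameters:
    """The published parameter set (with the reconstructed ``d_max``).

    tau1=20, tau2*=6.8, tau3=10, tau4=800, W11*=0.5588, W12*=0.786,
    W13=0.023, W21=0.339, a=0.15, W34=0.36, sigma=(0.05, 0.01, 0.001, 0.05).
    ``d_max`` is not published; the default is this package's reconstruction.
    """
    return ModelParameters(**overrides)
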