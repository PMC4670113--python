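"""Named simulation protocols used by the analysis pipelines.

Three protocols matter for this model:

``published_protocol``
    The printed integration recipe: dt = 0.001, 120000 steps (120 time
    units), N = 1e6 realizations started at the interior unstable fixed
    point.  Note that 120 time units is short against the dopamine
    relaxation time tau4 = 800, so the slow variable x4 is essentially
    frozen at its initial value under this protocol; distributions obtained
    with it are delay-period snapshots, not stationary laws.

``stationary_protocol``
    A quasi-stationary variant for landscape and robustness work: the
    horizon is extended to 2400 time units (3 tau4, so the slow dopamine
    mode is ~95% relaxed) with a coarser step dt = 0.05 (still 35x below
    the fastest relaxation time tau2(0) = 1.77, keeping the first-order
    weak error at the percent level).

``delay_protocol``
    The working-memory retention assay behind the SNR profiles: ensembles
    start in the sustained-firing (upper) state and run for one delay
    period of 120 time units; statistics then measure how well the memory
    state survives the delay.
"""

from __future__ import annotations

from .simulate import SimulationSettings

__all__ = ["published_protocol", "stationary_protocol", "delay_protocol"]


def published_protocol(n_realizations: int = 1_000_000, seed: int = 0) -> SimulationSettings:
    """The printed recipe: dt = 0.001, 120000 steps, N = 1e6."""
    return SimulationSettings(dt=0.001, n_steps=120_000,
                              n_realizations=n_realizations, seed=seed)


def stationary_protocol(n_realizations: int = 10_000, seed: int = 0,
                        horizon: float = 2400.0, dt: float = 0.05) -> SimulationSettings:
    """Quasi-stationary protocol: horizon 3 tau4 at dt = 0.05."""
    return SimulationSettings(dt=dt, n_steps=int(round(horizon / dt)),
                              n_realizations=n_realizations, seed=seed)


def delay_protocol(n_realizations: int = 10_000, seed: int = 0,
                   horizon: float = 120.0, dt: float = 0.02) -> SimulationSettings:
    """One delay period (120 time units) at dt = 0.02."""
    return SimulationSettings(dt=dt, n_steps=int(round(horizon / dt)),
                              n_realizations=n_realizations, seed=seed)
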