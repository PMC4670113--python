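# mesowm

Stochastic dynamics of the closed-loop mesocortical circuit that maintains
working memory across a delay period.

During delayed-response tasks, sustained firing in the dorsolateral
prefrontal cortex (DLPFC) holds a memory across the delay while midbrain
dopaminergic neurons, themselves excited by the DLPFC, feed dopamine back
into it — a closed loop in which D1-receptor activation tunes the cortical
circuitry that generates the sustained firing.  `mesowm` implements a
four-variable rate model of this loop for computational neuroscientists who
want to ask: *how robust is the memory state against background noise, and
how does that robustness depend on dopamine releasability?*

## The model

State `x = (x1, x2, x3, x4)`: DLPFC pyramidal activity, DLPFC interneuron
activity, midbrain dopaminergic activity, DLPFC dopamine content.

```
dx1 = [ -x1/tau1    + W11(d) g(x1) - W21 g(x2) ] dt + sigma1 dW1
dx2 = [ -x2/tau2(d) + W12(d) g(x1)             ] dt + sigma2 dW2
dx3 = [ -x3/tau3    + W13 g(x1)                ] dt + sigma3 dW3
dx4 = [ -x4/tau4    + W34 g(x3)                ] dt + sigma4 dW4
```

with saturation `g(x) = tanh(a x)` for `x >= 0` (else 0), D1 activation
`d = d_max g(x4)`, and affine D1 modulation `W11(d) = W11*(0.12 d + 0.68)`,
`W12(d) = W12*(0.12 d + 0.68)`, `tau2(d) = tau2*(0.24 d + 0.26)`.  The
dopamine releasability `W34` is the bifurcation parameter, quoted as % of
its baseline 0.36.

The package provides, as separate layers over this model:

- **equilibrium analysis** — all fixed points at a given `W34` (the scalar
  self-consistency reduction plus Brent refinement), stability from the
  analytic Jacobian, and the bifurcation diagram with landmarks **P**
  (fold where bistability appears), **Q** (maximum upper-branch pyramidal
  activity) and **R** (maximum upper-branch interneuron activity), which
  partition the axis into zones I–IV;
- **stochastic simulation** — seeded, batch-independent Euler–Maruyama
  ensembles (numba-compiled), plus an exact Ornstein–Uhlenbeck reference
  (Lyapunov-equation stationary covariance) for validation;
- **potential landscapes** — `U = -ln P_st` over sampled marginals, well
  depths and the inter-well barrier split at the unstable point's x1
  (the operational separatrix), and the robustness profile `U_high(W34)`;
- **SNR analysis** — mean/SD of pyramidal and midbrain activity,
  conditional on basin and unconditional, over a `W34` sweep under a
  delay-period retention protocol.

See `docs/methods.md` for the assumptions, the reconstructed `d_max`
constant, simulation protocols and known limitations.

## Worked example

```python
import numpy as np
from mesowm import (paper_defaults, find_fixed_points, bifurcation_scan,
                    default_w34_grid, snr_profile, W34_BASELINE)
from mesowm.protocols import delay_protocol

params = paper_defaults()          # printed constants, reconstructed d_max=3.5

# fixed points at baseline releasability (100% of 0.36)
for fp in find_fixed_points(0.36, params):
    print(fp)
# FixedPoint([0, 0, 0, 0], d=0, stable)
# FixedPoint([0.1385, 0.022, 0.004776, 0.2063], d=0.1083, unstable)
# FixedPoint([1.424, 0.468, 0.04841, 2.091], d=1.063, stable)

# bifurcation landmarks over the default sweep (30-160% of 0.36)
diagram = bifurcation_scan(default_w34_grid(), params)
lm = diagram.landmarks
print({k: f"{100 * v / W34_BASELINE:.1f}%" for k, v in
       {"P": lm.P, "Q": lm.Q, "R": lm.R}.items()})
# {'P': '38.1%', 'Q': '85.0%', 'R': '127.0%'}

# SNR of the memory state across one noisy delay period
grid = W34_BASELINE * np.arange(40.0, 161.0, 15.0) / 100
prof = snr_profile(grid, params, delay_protocol(n_realizations=10_000, seed=7))
print(f"SNR(x1) peaks at {100 * prof.peak_w34('x1') / W34_BASELINE:.0f}%")
# SNR(x1) peaks at 85%
```

The three fixed points are the spontaneous-activity state (origin), the
threshold saddle, and the sustained-firing state whose pyramidal activity
`x1 = 1.42` represents the held memory.  The fold P at 38.1% is the minimum
releasability able to sustain a memory at all; pyramidal activity peaks at
Q = 85% and interneuron activity at R = 127%.  The SNR of pyramidal firing
across a delay period is maximal near baseline releasability and falls
steeply below it, where the memory state collapses mid-delay — the
inverted-U profile of dopaminergic working-memory modulation.

A command-line layer mirrors the library:

```sh
mesowm bifurcation --w34-range 30 160 1 --out runs/bif
mesowm snr --w34-range 40 160 15 --n-realizations 10000 --seed 7 --out runs/snr
```

Every run directory contains CSV/JSON outputs, the exact configuration and
a manifest with file checksums for bit-identical re-runs.

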