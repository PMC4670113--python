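# Methods

## The model

The package implements a four-variable rate model of the closed-loop
mesocortical circuit underlying delay-period working memory.  The state is
`x = (x1, x2, x3, x4)`: population activity of DLPFC pyramidal neurons
(`x1`) and GABAergic interneurons (`x2`), activity of midbrain dopaminergic
neurons (`x3`), and DLPFC dopamine content (`x4`).  The deterministic drift
is

```
f1 = -x1/tau1    + W11(d) g(x1) - W21 g(x2)
f2 = -x2/tau2(d) + W12(d) g(x1)
f3 = -x3/tau3    + W13    g(x1)
f4 = -x4/tau4    + W34    g(x3)
```

with the saturation `g(x) = tanh(a x)` for `x >= 0` and `0` for `x < 0`,
D1-receptor activation `d = d_max g(x4)`, and the affine D1 modulation

```
W11(d) = W11* (0.12 d + 0.68)
W12(d) = W12* (0.12 d + 0.68)
tau2(d) = tau2* (0.24 d + 0.26)
```

All quantities are dimensionless; time is dimensionless model time.  The
default constants are `tau1 = 20`, `tau2* = 6.8`, `tau3 = 10`, `tau4 = 800`,
`W11* = 0.5588`, `W12* = 0.786`, `W13 = 0.023`, `W21 = 0.339`, `a = 0.15`,
with baseline releasability `W34 = 0.36` and additive noise strengths
`sigma = (0.05, 0.01, 0.001, 0.05)`.  The cue/phasic/tonic input currents of
the ancestral circuit model are intentionally absent: they shape transients,
not the equilibrium structure studied here.

The Langevin form adds independent delta-correlated Gaussian noise to each
equation, `dx_i = f_i dt + sigma_i dW_i`, integrated with fixed-step
Euler-Maruyama.  States are not clamped at zero: negative excursions decay
through the linear leak terms, and only the saturation clamps their
*effect* on other variables.

## Reconstructed and ambiguous quantities

Two constants of the modulation rules are not fully pinned down by the
published description; both are configurable, and every run manifest
records them as caveats.

**`d_max`.**  The D1 ceiling appears only inside `d = d_max g(x4)`.  We
expose it as a configuration parameter with default **3.5**.  The value was
chosen once, on deterministic grounds, so that the bifurcation landmarks
bracket the baseline releasability: with `d_max = 3.5` the fold sits at
P ≈ 38% of 0.36, the upper-branch pyramidal maximum at Q ≈ 85%, and the
interneuron maximum at R ≈ 127%, so 100% releasability falls between Q and
R, where the robustness and SNR optima live.  Larger ceilings shift the
whole landmark structure to lower percentages (for `d_max = 5`, 100% lies
beyond R), smaller ones push R outside any practical sweep.  All landmark
locations therefore depend on the configured `d_max` and are reported, not
hard-coded.

**The `tau2` modulation variable.**  The published rule
`tau2 = tau2*(0.24 z + 0.26)` is written in an otherwise undefined variable
`z`, while the surrounding description says the interneuron time constant
*decreases* with D1 stimulation — which the formula, read with `z = d`,
does not do.  We implement `z = d` (the only free modulatory level in the
model); the textual inconsistency is recorded in the run manifest rather
than silently "corrected", because the `z = d` reading is what produces the
interneuron maximum R *after* the pyramidal maximum Q — the modulation
factor of the inhibitory drive `x2* = tau2(d) W12(d) g(x1)` grows
quadratically in `d` while the excitatory drive grows linearly, and that
race is precisely what bends the upper branch down between Q and R.

## Equilibrium analysis

At equilibrium the three last equations back-substitute into the first,
reducing `f(x*) = 0` to a scalar equation in `x1`.  Roots are isolated by
sign changes on a uniform grid (2000 points over `[0, 30]` by default) and
polished with Brent's method; the origin, which is an equilibrium for every
parameter set, is always included.  Stability comes from the analytic
Jacobian; because `g` has a kink at 0 the Jacobian is only defined on the
open positive orthant, so the origin is classified by its one-sided
linearization with `g'(0+) = a` (it is stable, marginally so: the leading
eigenvalue pair has a determinant of order 1e-4, which makes the
spontaneous state a broad, weakly confined cloud under noise — a property
that shapes everything stochastic below).  Eigenvalue real parts within
1e-8 of zero yield "non-classifiable" rather than a silent stability call.

The fold P is refined by bisection on the 1-to-3 root-count transition to a
W34 tolerance of 1e-5.  Q and R are grid argmaxima of the upper branch.
The default sweep is 30%-160% of 0.36 in 1% steps — wider than a
half-to-one-and-a-half window so that zone I and the fold are inside the
default scan with the default `d_max`.

## Simulation protocols

The published integration recipe is `dt = 0.001`, 120000 steps and
N = 1e6 realizations started at the interior unstable fixed point.  Its
horizon is 120 time units — *seven times shorter* than the dopamine
relaxation time `tau4 = 800`.  Under this protocol the slow variable
`x4` (hence `d`) barely moves from its initial value: the resulting
distributions are delay-period snapshots conditioned on the initial
dopamine level, not stationary laws, and the upper-basin sample mean sits
well below the deterministic upper branch.  The package therefore names
three protocols (`mesowm.protocols`) and uses each where it is the right
tool:

- `published_protocol` — the printed recipe, kept as the reference.
- `stationary_protocol` — horizon 2400 time units (3 tau4, the slow mode
  ~95% relaxed) at `dt = 0.05`, provided for genuinely steady-state
  questions.  The coarser step is 35x below the fastest relaxation time
  `tau2(0) = 1.77`; note that the well-potential difference
  `U_high - U_low` carries a measurable O(dt) discretization bias (~0.1
  between dt = 0.05 and dt = 0.01 at equal horizons), so cross-protocol
  comparisons of small potential differences need matched steps.
- `delay_protocol` — one delay period (120 time units) at `dt = 0.02`,
  started at the *upper* (sustained-firing) fixed point.  Used for the SNR
  profiles, which ask a retention question: how well does the
  working-memory state survive one noisy delay period?  At low
  releasability a large fraction of realizations collapses to the
  spontaneous state within the delay, dragging the unconditional mean down
  and inflating the spread — the low-W34 limb of the inverted-U.

Reproducibility: realization `r` of an ensemble uses the Mersenne-Twister
sub-stream seeded with `(seed + r * 0x9E3779B1) mod 2^32`, so results are
bit-identical for a fixed seed regardless of batching.  A burn-in
diagnostic (drift of ensemble means over the tail of thinned trajectories)
is available through `record_every`.

## Potential landscapes and robustness

`U = -ln P_st` is computed per occupied bin of the sampled distribution;
empty bins carry no potential (they are excluded, not infinite).  Basins
are split at the x1 coordinate of the interior unstable fixed point — the
operational stand-in for the intractable 4-D separatrix, consistent with
presenting landscapes on the x1 marginal.  Wells are per-basin minima of U,
the barrier is the maximum of the x1-marginal potential between the well
bins (a marginal barrier, not a minimum-energy path), and all comparisons
are potential differences, invariant to rescaling of the probabilities.
Default binning: 100 uniform x1 bins on a fixed range (edges recorded in
all outputs), 60x60 for the x1-d joint marginal.

The robustness profile integrates an ensemble at each W34 of a bistable
grid (the delay-horizon protocol by default, matching the printed recipe;
any protocol can be passed) and records `U_high`, `U_low` and the
barrier.  Because the
Monte-Carlo scatter of a well potential at practical ensemble sizes is
comparable to the curvature of the profile, the location of maximum
robustness `w34*` is read from a quadratic fit through the sampled
`U_high` points (the raw grid argmin is also reported).

## SNR analysis

The SNR of a variable is mean/standard-deviation (population convention;
the mean/variance rendering is available behind a flag).  Samples are
labeled upper/lower by the x1 separatrix, ties to lower; conditional
statistics require at least 100 samples in a basin, otherwise the value is
flagged NaN rather than reported.  Profiles are computed for x1 and x3
with the delay protocol and report, per grid point: conditional moments
and SNR per basin, unconditional moments and SNR, basin occupancies, and
the deterministic upper-branch value as the signal reference.  The
unconditional statistics are the headline profile: they are what detects
the collapse of the memory state at low releasability (the conditional
upper-basin statistics, truncated at the separatrix, stay high right up to
the fold).

## What the simulations do and do not show

The ensembles are generated by the model itself, so passing tests show
internal consistency of the pipeline (integrator vs exact
Ornstein-Uhlenbeck laws, root-finder vs brute-force scans, landscape
identities) and reproduction of the qualitative structure of the circuit's
behavior: the monostable-to-bistable transition, the ordering P < Q < R,
the lower-to-upper occupancy shift with rising releasability, the
inverted-U SNR profile with its steeper low-releasability limb.  They do
not show anything about biological dopamine levels or real DLPFC firing:
the model is a minimal rate description with hand-set constants, additive
white noise, and a reconstructed D1 ceiling.

Numerical scale choices: analysis ensembles default to N = 1e4
realizations (1e6 in the printed recipe); tests use N in the hundreds to
thousands.  The quantitative well-potential differences at these ensemble
sizes carry Monte-Carlo errors of a few times 0.01-0.1 in U; all tests and
profiles are designed around sign and ordering properties rather than
absolute U values.

## Known limitations

- The near-marginal spontaneous state (leading determinant ~1e-4 at d = 0)
  makes the lower basin a weakly confined cloud; its sampled "well depth"
  converges slowly with horizon, and short-horizon landscapes
  systematically favor it.
- The relative well depths are delicate: with the default noise strengths,
  `U_high - U_low` is of order 0.1 or less across much of the bistable
  range under either protocol, so its *sign* at a single W34 needs
  ensembles well beyond 1e4 realizations to pin down.  Ordering statements
  along the W34 axis (occupancy shift, U_high decline, SNR asymmetry) are
  far better conditioned than pointwise sign statements, and the profile
  analyses are designed around them.
- The x1-separatrix basin rule misassigns rare samples mid-transit.
- No Fokker-Planck solution, no Kramers rates, no limit-cycle or
  codimension-2 analysis; bistability beyond the scanned W34 window is not
  extrapolated.
- `d_max` is a reconstruction; all landmark percentages move with it.
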