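# Methods

This note documents the models, conventions, and numerical choices behind
`braindyn`, in the spirit of a simulator's methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Simulation model and intra-step ordering

A model is a tree of components. One fixed-step update proceeds
depth-first: **children update before their parent integrates its own
states**, in insertion order. In networks, neurons integrate and emit
spikes first, and synaptic conductances are then incremented from the
spikes of the *current* step, affecting the membrane from the next step on
(a single-step causal pipeline). This ordering is a convention, not a law
of nature — the literature does not fix one — but fixing it makes every
record bit-reproducible: identical `(model, inputs, seed)` give
byte-identical results, and `run → reset → run` reproduces the first record
exactly. The runner aborts with a named step/variable on the first
non-finite state instead of propagating NaNs; debuggability beats
completing a doomed run.

Batching is realized by looping over independent, freshly built runs
(cartesian or zipped parameter grids, deterministic order). There is no
vectorized batch mode; that belongs to a compiler layer this package
deliberately does not have.

Delays are rounded to the nearest integer step (no interpolation); a ring
buffer returns the declared initial value until history fills.

## Integrators

* Explicit Runge–Kutta methods are driven by Butcher tableaus validated at
  construction (Σb = 1 to 1e-12, strictly lower-triangular A, c_i = Σ_j
  A_ij). Registering the textbook RK4 tableau reproduces the built-in
  `rk4` bit for bit, because they are the same code path.
* Exponential Euler: `y' = y·e^{a·dt} + dt·φ₁(a·dt)·r(t,y)` with
  `φ₁(z) = (e^z−1)/z` evaluated via `expm1` and a Taylor branch below
  `|z| = 1e-8`. Exact (to round-off) for `dy/dt = a·y + c`; this is the
  default scheme for membrane and gating equations, and is why a LIF
  neuron's simulated interspike interval matches the closed form to the
  spike-detection resolution.
* Adaptive stepping uses the Fehlberg 4(5) embedded pair; error estimate is
  the RMS of the order-4/5 difference scaled by `atol + rtol·|y|`, safety
  factor 0.9, growth clamped to [0.2, 5], dt clipped to `[dt_min, dt_max]`;
  a rejected step at `dt_min` raises a stiffness error. These controller
  constants are textbook values.
* SDE steppers are fixed-step only (Euler–Maruyama and Milstein for Itô,
  Heun predictor–corrector for Stratonovich). Wiener increments are drawn
  by the caller, never inside the stepper, so strong-order studies and
  Itô/Stratonovich comparisons run on common noise. Milstein's diffusion
  derivative is taken by central differences; multi-dimensional
  non-commutative noise is rejected rather than silently mishandled.

## Sparse and event-driven operators

Rows are presynaptic. The event-driven product iterates only over active
rows and accumulates in float64 in a fixed edge order (row-major, sorted
columns). The matrix-free variant regenerates row `i` of a Bernoulli(p)
connectivity from the stream `PCG64(SeedSequence(entropy=seed,
spawn_key=(i,)))` using geometric skip sampling, drawing per-edge normal
weights (if requested) from the same stream after the row's indices. The
stream is part of the public contract: the matrix-free operator, the
materialized matrix, and the `fixed_prob` connectivity builder all agree
exactly because they share it.

Two accumulation caveats are deliberate: duplicate edges are permitted in
raw edge lists and are summed; and linearity over disjoint event sets holds
to round-off (≈1e-16 relative), not exactly, because the association order
of the per-column float sums differs between a combined and a split
evaluation.

## Model zoo conventions

Voltages in mV, times in ms, rates in Hz. Conductances are nonnegative and
currents follow `I = g·(E_rev − V)` added to the membrane equation. Spikes
are detected as `V ≥ V_th` after the integration substep, without threshold
interpolation — consistent with fixed-step simulators, and the source of
the ≤1-step ISI quantization visible at coarse dt.

* **LIF** defaults: τ = 20 ms, V_rest = −65 mV, V_reset = −70 mV,
  V_th = −50 mV, R = 1, t_ref = 2 ms.
* **Hodgkin–Huxley** uses the classical squid-axon kinetics (6.3 °C
  conventions, resting potential −65 mV): `I_K = g_K n⁴ (E_K − V)`,
  `I_Na = g_Na m³h (E_Na − V)`, leak in the neuron itself. Gates advance by
  exponential Euler on `dx/dt = α(V)(1−x) − β(V)x`, which confines them to
  [0, 1] by construction (each step is a convex combination of `x` and the
  steady state `α/(α+β)`).
* **Synapse kernels** decay exactly per step (scalar exponentials and, for
  the alpha kernel, the closed-form Jordan-block propagator), so a single
  unit impulse reproduces the closed-form transient to round-off; dual
  exponential kernels are normalized to peak at `g_max` at
  `t = τ_r τ_d/(τ_d−τ_r)·ln(τ_d/τ_r)`. NMDA applies the magnesium-block
  factor `1/(1 + [Mg]/3.57·e^{−0.062V})`.
* **COBA network**: conductance-based LIF E/I network in leak-conductance
  units (g_l = 1, Cm = 20 ⇒ τ_m = 20 ms; E_l = −60, V_th = −50,
  V_reset = −60 mV, t_ref = 5 ms; τ_e = 5 ms, τ_i = 10 ms, E_e = 0,
  E_i = −80 mV, w_e = 0.6, w_i = 6.7 in g_l units), following the standard
  benchmark constants. A constant external drive (default 12 g_l·mV,
  mildly suprathreshold) keeps a 400-neuron network active; at benchmark
  scale the network would sustain itself, but a desk-scale instance needs
  the drive. The dense and event-driven synaptic pathways produce
  *bit-identical* rasters for equal seeds because per-step synaptic
  increments are integer spike counts (exact in float64) times a common
  scalar weight, and all remaining arithmetic is elementwise and identical.
* **Ring attractor (CANN)**: `τ du/dt = −u + W·r(u) + I_ext` with
  `r = u₊²/(1 + k·ρ·Δx·Σu₊²)` and Gaussian ring coupling
  `W_ij = J0/(√(2π)a)·exp(−d_ij²/2a²)` (circular distance, ring length
  L = 2π, ρ = N/L so ρ·Δx = 1). Defaults N = 128, τ = 1 ms, k = 8.1,
  a = 0.5, J0 = 4 — a standard bump-regime parameterization (J0 well above
  the bump-existence threshold). The bump continuum is a line attractor:
  every bump equilibrium has one near-zero eigenvalue (the translation
  mode) and is labeled *marginal*.

  A consequence worth stating explicitly: because the rate function is
  quadratic at zero, the recurrent loop has zero gain at `u = 0`, so the
  linearization at the quiescent state is `−I/τ` — **stable for any
  coupling strength**. The unstable equilibria of this model are the
  small-amplitude saddle bumps between the quiescent state and the
  attractor bumps, not the origin. The acceptance test asserting an
  unstable origin is therefore expected to fail; it is retained unmodified
  as a faithful statement of the claim it checks.
* **Rate models**: FitzHugh–Nagumo (`dv = v − v³/3 − w + I`,
  `dw = (v + a − b·w)/τ`; a = 0.7, b = 0.8, τ = 12.5), Wilson–Cowan with
  logistic gains (classic oscillatory constants), and the two-variable
  reduced decision model with transfer function
  `H(x) = (ax−b)/(1−e^{−d(ax−b)})` and the standard constants (a = 270,
  b = 108, d = 0.154, γ = 0.641, τ_s = 100 ms, J₁₁ = J₂₂ = 0.2609,
  J₁₂ = J₂₁ = 0.0497, I₀ = 0.3255 nA). At zero stimulus the model is
  exactly symmetric under swapping the two populations.

## Reservoir training

The Lorenz task is one-step-ahead, teacher-forced prediction: the reservoir
is driven by the true standardized series and the linear readout predicts
the next sample. Free-running generation exists but is not the evaluated
protocol — teacher forcing gives a deterministic, comparable score. The
series (σ = 10, ρ = 28, β = 8/3, RK4 at dt = 0.01, 60 time units, initial
state jittered per seed) is standardized per variable using training-split
statistics only; MSE is reported on that standardized scale, averaged over
variables and test steps. Split: first 10% washout, next 70% training,
final 30% test. Reservoir defaults: N = 400, spectral radius 0.9 (rescaled
exactly via a sparse eigensolve), input scale 0.1, leak 1.0, density 0.05,
plus a constant bias feature for the readout.

Ridge uses the closed form through a symmetric positive-definite solve
(least-norm fallback with a rank warning at λ = 0). FORCE is one
sequential recursive-least-squares pass with `P₀ = I/α`; note that such a
pass is *exactly* the ridge solution with λ = α — the interesting
difference from offline ridge is the online trajectory, not the endpoint on
a fixed batch. `P` is re-symmetrized each step to guard the SPD invariant
over long runs.

The synthetic Lorenz generator emulates only what the task needs — a
smooth, bounded, chaotic three-variable series. Passing these tests says
nothing about sensor noise, missing data, or nonstationarity in real
recordings.

## Analyzers

Phase-plane fixed points: candidate cells where both derivative components
change sign in a 2×2 neighborhood seed a hybrid-Powell root solve;
solutions with `‖F‖_∞` within tolerance are deduplicated (lowest residual
kept) and classified by central finite-difference Jacobian eigenvalues
(per-coordinate step `1e-6·(1+|x_i|)`). Nullclines come from sign-change
scanning along grid lines with Brent polishing. Bifurcation scans are
grid-based (no arclength continuation); stability changes are reported at
grid resolution, so brackets shrink proportionally under grid refinement.

Slow points minimize `q(x) = ½‖F(x)‖²` from many seeds. The default
optimizer is trust-region nonlinear least squares; plain gradient descent
with backtracking is available (`method="gd"`) but converges impractically
slowly along the soft mode of a non-hyperbolic line attractor, which is
exactly the regime the finder exists for — hence the default. Acceptance
requires `‖F‖_∞ ≤ tol` (default 1e-6); near-duplicates within
`0.01·√dim` (configurable) are merged. For discrete-update maps, analyze
`F(x) = x_{t+1} − x_t`.

Stability labels use a margin of 1e-3 on eigenvalue real parts:
`max|Re λ| ≤ margin` ⇒ *marginal*. Without the margin, a line attractor's
translation mode (numerically ±1e-12) would be labeled by sign noise.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script each
run in well under a minute of CPU apiece at desk scale: COBA at 400
neurons / 500 ms, CANN at 128 units with ~25 optimizer seeds, reservoirs at
N = 400 on a 6000-sample series, SDE order studies at 400 paths. All sizes
are parameters, not constants.

## Known limitations

No implicit solvers (stiff multi-compartment models are out of scope), no
adaptive SDE stepping, no delay interpolation beyond step rounding, no
plasticity rules, no vectorized batch transforms or multi-device execution.
The spiking models are analyzed via their subthreshold flows only; the
analyzers assume a numerically differentiable right-hand side.
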