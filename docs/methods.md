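# Methods

This note documents the models, numerical choices and design decisions
behind `ectopy`, and what its synthetic inputs do and do not emulate.

## Cell model

The generalized FitzHugh–Nagumo cell is

    tau1 dV/dt = V - V^3/3 - W + d + I
    tau2 dW/dt = V + a - b W

with defaults `a = 1.25`, `d = 0.6`, `tau1 = 10 ms`, `tau2 = 400 ms`,
`I = 0`. `V` and `W` are dimensionless; time is in milliseconds everywhere.
The constants place the nullcline intersection at the left knee of the
cubic, `(V, W) = (-1.25, 0)`, which makes the cell excitable, and the time
constants shape the excursion like a cardiac action potential. The recovery
decay rate `b` is the biological knob: it shortens the lifetime of the
repolarizing current, prolonging the action potential until a depolarized
up-state stabilizes and the cell becomes bistable. `b > 0` is enforced
(non-positive `b` lets `W` grow without bound).

Equilibrium potentials are the real roots of the cubic
`V - V^3/3 - (V+a)/b + d + I = 0`, solved in closed form (trigonometric /
Cardano by discriminant sign) and polished with a few Newton steps to
~1e-12 residual; stability comes from the eigenvalues of the analytic 2x2
Jacobian. Stimuli are additive square pulses inside `dV/dt`, default
amplitude 2 for 15 ms. Single-cell trajectories use adaptive RK45 with
1e-6 absolute and relative tolerances, with integration restarted at pulse
edges so the discontinuity is never stepped over.

## Continuation

`continue_in_b` follows the equilibrium branches with a pseudo-arclength
predictor–corrector (secant predictor, Newton corrector orthogonal to the
tangent, step adapted between 0.01 and 0.1, corrector tolerance 1e-6).
Saddle-node candidates are flagged by a sign change of
`1 - b (1 - V^2)` (proportional to det J) and Hopf candidates by a sign
change of the trace `(1 - V^2)/tau1 - b/tau2` with positive determinant;
each is localized by bisection along the branch to better than 1e-3 in `b`.
Two independent closed-form conditions are used as cross-checks throughout
the tests: at a fold `1 - V^2 = 1/b`, at a Hopf `1 - V^2 = b tau1/tau2`,
each jointly with the equilibrium cubic. With default parameters the fold
sits at `b = 1.640` and the Hopf at `b = 1.759`; the quoted single-cell
bistability onset of 1.76–1.77 is this Hopf point to two decimals.

The reduced model replaces the neighborhood of one cell with `n` identical
cells clamped at `Vr = -1.25`, contributing gap current `n c^2 (Vr - Vo)`.
Substituting the Hopf (zero-trace) condition
`n c^2 = 1 - Vo^2 - b tau1/tau2` into the equilibrium equation leaves one
cubic in `Vo` per value of `b`, so the Hopf curve is traced by natural
continuation in `b` (steps of 0.05, well under the 0.1 spacing bound),
seeded at the single-cell Hopf where `c -> 0` and selecting the up-state
root nearest the previous point. Determinant positivity holds along the
curve for `b < sqrt(tau2/tau1) ~ 6.3`, which brackets the scanned range
`b in [1.77, 6]`. Classification of a configuration `(b, c, n)` is by
direct equilibrium solving and eigenvalues (bistable iff at least two
stable equilibria); the `StabilityMap` object classifies by interpolating
the curve and agrees with the direct route on the reference configurations.
Limit cycles are not continued and the first Lyapunov coefficient is not
computed; only equilibria are tracked.

## Medium

The sheet is the method-of-lines system on a regular grid with `dx = dy = 1`
and isotropic diffusion `c^2 (Vxx + Vyy)` discretized by second-order
central differences. Neumann edges use mirror substitution (the ghost cell
copies the edge cell); periodic edges wrap. Internal tissue boundaries use
per-cell, per-direction flux masks: a masked direction substitutes the
cell's own value for the neighbor, zeroing the flux across that edge, and
masks are validated to be symmetric across every shared edge. Cells inside
an annulus are absent tissue: fully masked, frozen in time, excluded from
stimuli and statistics. With these closures the discrete Laplacian sums to
zero over the grid (no-flux conservation), which the tests assert to 1e-10.

The default integrator is a fixed-step classical RK4 numba kernel. Step
sizes: `dt = 0.1 ms` for the Monte-Carlo trials (the statistics below were
generated at this step), `dt = 0.2 ms` for the long narrative runs (6–10 s
of simulated time on grids up to 100x300). Both are far inside the RK4
stability region for this system and were chosen by step-halving studies:
halving `dt` moves wave arrival times by well under 1% and leaves outcome
classifications and failure counts unchanged. An adaptive reference path
(RK45 at 1e-6 tolerances on the flattened system) is kept for validation on
small grids. A non-finite field at any segment boundary raises an error
carrying the failure time.

Initial conditions: tissue simulations start from the nominal uniform rest
`(V, W) = (-1.25, 0)`, which is within ~1e-3 of every cell's true resting
equilibrium across the `b` ranges used; `resting_field` also offers the
exact per-cell equilibrium (vectorized Newton) used by the equilibrium-
invariance tests. "Left-hand boundary" stimulation means the first grid
column; "uniform" means all tissue cells.

## Heterogeneity generators

Binary mixtures draw each cell i.i.d. bistable with the given probability
(`b_bi = 3` among `b_mono = 1` by default). Nested draws (for superset
experiments) threshold one uniform field at several fractions, so larger
fractions contain smaller ones by construction. Log-normal fields take
`b = exp(N(mu, sigma^2))`; this parameterization (mean/SD of the underlying
normal) reproduces the analytic bistable fractions
`P(b > 1.77) = 0.629, 0.666, 0.702` for `mu = 0.9, 1.0, 1.1` at
`sigma = 1`, which a moment parameterization would not. All generators are
reproducible: the same spec and seed give bitwise-identical fields.

The annulus is rasterized as a filled disk of absent cells from cell-center
Euclidean distance (ties at the radius are inside). The radii are a free
geometric choice; the default is radius 10 centered in the grid (center at
`((rows-1)/2, (cols-1)/2)`, i.e. 19.5 in a 40x40 grid, which keeps the
rasterization four-fold symmetric). Every rim cell then has 2 or 3 live
neighbors, the neighbor-count deficit that makes boundaries vulnerable.
"Boundary" cells are tissue cells 4-adjacent to the hole; everything else
is "midfield". No spatially correlated heterogeneity or fibrosis texture is
modeled.

## Monte-Carlo trials

One trial: draw a fresh b-field over fixed geometry (a 40x40 periodic grid
with the central annulus by default), start at rest, stimulate all tissue
cells with `I = 2` for 15 ms, integrate to 1000 ms, and score every tissue
cell with `V > 0` as a repolarization failure. Trials use independent child
seeds of the master seed, so a summary is exactly reproducible. Two
standard errors are reported for each region rate: the standard error of
the per-trial region means across trials (the headline estimator) and the
pooled binomial SE, which differ when failures are spatially correlated
within a trial. Radial profiles bin tissue cells by integer-rounded
distance from the annulus center. Adjusted rates divide an observed rate by
the density of intrinsically abnormal cells, giving the failure rate of the
abnormal cells themselves.

Wavefront scenarios stimulate the left column, sample the depolarized set
every 10–50 ms, and classify the run as sustained ectopy if any tissue cell
is depolarized at the end of the run. Cells are tracked by depolarization
streaks: a cell continuously above threshold for 700 ms (about four
homogeneous action-potential durations) can no longer be a normal
excursion, and cells whose streak persists through the end of the run are
permanent ectopic sources; the earliest-onset such cells are reported as
the genesis of the ectopy.

## Biophysical (Qu–Chung) model

The ventricular cell follows the Luo–Rudy phase-1 formulation:
`dV/dt = I_stim - (I_Na + I_CaL + I_K + I_K1 + I_Kp + I_b)` in mV, ms and
uA/uF (capacitance normalized to 1), with the published rate constants for
the gates m, h, j, x, the `Xi` rectification factor, `K1_inf` and the
plateau gate. Table constants: `[K]o = 5.4`, `[K]i = 145`, `[Na]o = 140`,
`[Na]i = 10`, `[Ca]o = 1.8` mM, `RT/F = 26.71 mV`, conductances
`g_Na = 16`, `g_CaL = 0.09`, `g_K = 0.282`, `g_K1 = 0.3` (deliberately
reduced from 0.6047 to lower the firing threshold), `g_Kp = 0.0183`,
`g_b = 0.0392`. Calcium follows
`d[Ca]i/dt = -1e-4 I_CaL + 0.07 (1e-4 - [Ca]i)`.

Two modifications produce bistable action potentials: `gamma` multiplies
`tau_x` (slowing delayed-rectifier activation by `1/gamma`), and the
L-type steady states are replaced by
`d_inf = 1/(1 + exp(-(V + V0)/9.4))` and
`f_inf = 1/(1 + exp((V + V0 + Delta)/7.2))` with `V0 = 24.5 mV`. The sign
in the `f_inf` exponent is chosen so that f *inactivates* with
depolarization; a negative `Delta` then moves the inactivation midpoint to
more depolarized voltages, widening the I_CaL window current. This is the
convention under which the isolated cell with `gamma = 4, Delta = -15`
parks on a plateau near -15 mV and never repolarizes, while the default
cell fires a ~420 ms action potential — the behavior the modifications are
meant to produce; the opposite sign closes the window and cannot fail.

Single cells are integrated with adaptive LSODA (rtol 1e-6, atol 1e-8).
Sheets use a numba kernel with Rush–Larsen exponential gate updates on
voltage-tabulated kinetics (4801-point tables over [-120, 120] mV, linear
interpolation) and forward-Euler membrane/calcium updates at `dt = 0.02 ms`
(halving to 0.01 ms changes the bulk of the final voltage field by well
under 0.5 mV and no outcome classifications). Coupling is the same masked
5-point Laplacian with coefficient `c^2` and Neumann edges. The stimulus
amplitude is a tunable (default 80 uA/uF for 0.5 ms, sufficient to launch
exactly one rightward wave); a stimulus quoted in pA cannot be mapped onto
the normalized-capacitance units without a cell-size assumption, so the
amplitude is treated as a free protocol parameter. APD90 is
measured from stimulus onset to the last time the voltage sits above
`V_rest + 0.1 (V_peak - V_rest)`; a trace still above that level at the
horizon is flagged as a repolarization failure.

## What the synthetic inputs do not capture

The generators emulate the modeled conditions — binomial mixtures, log-normal
`b`-fields with the stated moments, the annulus boundary — not real
myocardium: there is no spatial correlation in cell properties, no fiber
anisotropy, no restitution in the FHN cell, and no calcium-overload
pathology. Passing tissue-level tests therefore demonstrates the dynamical
mechanism under idealized heterogeneity, not a quantitative prediction for
real tissue.

## Known limitations

* The sheet-level verification in the biophysical model reproduces the
  qualitative transition (a heavily bistable sheet sustains ectopy — a
  homogeneous bistable sheet does so trivially — while moderately bistable
  sheets repolarize), but the transition sits above a 60% bistable fraction
  here: at coupling `c = 0.15` the 40% mixtures are drained back to rest
  within ~4–5 s. The plateau-versus-drain balance is sensitive to
  Luo–Rudy transcription details that are not uniquely pinned down; the
  end-to-end test expecting sustained ectopy at 40% is left failing rather
  than weakened.
* In dense log-normal media with Neumann outer edges, the first permanent
  ectopic sources in this implementation usually root at the outer domain
  boundary (edge and corner cells also have reduced neighbor counts) or at
  extreme-`b` clusters, rather than specifically at the annulus rim; the
  annulus-first expectation is likewise encoded in a test that documents
  the discrepancy. The statistical boundary preference itself (elevated
  failure rates on rim cells versus midfield under uniform stimulation)
  reproduces clearly.
* Rotor/phase-singularity tracking, frequency analysis, limit-cycle
  continuation and 3-D geometry are out of scope.
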