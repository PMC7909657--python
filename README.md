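# ectopy

Arrhythmogenesis from bistable cardiac action potentials: a simulation and
bifurcation-analysis package for heterogeneous excitable media.

## The problem

Most accounts of cardiac arrhythmia initiation invoke after-depolarizations
as the trigger. An alternative mechanism is a cell that simply *fails to
repolarize* after a normal beat: if its membrane dynamics admit a second
stable equilibrium at depolarized voltage (an *up-state*), the cell can park
there and re-excite its neighbors once they recover, seeding fibrillation.
This package implements the computational machinery to study that mechanism:

* **Single cell** — a generalized FitzHugh–Nagumo (FHN) cell

  ```
  tau1 dV/dt = V - V^3/3 - W + d + I
  tau2 dW/dt = V + a - b W
  ```

  with `a = 1.25, d = 0.6, tau1 = 10 ms, tau2 = 400 ms`. The recovery decay
  rate `b` controls repolarization reserve: raising `b` prolongs the action
  potential until a stable up-state appears and the cell becomes bistable.

* **Continuation** — pseudo-arclength tracking of the equilibrium branches
  in `b` with saddle-node and Hopf detection, and the *reduced model*: one
  cell coupled to `n` neighbors clamped at rest (`Vr = -1.25`) through gap
  conductance `c^2`, whose Hopf point traced through the `(b, c)` plane
  yields a stability map separating configurations that always repolarize
  from those that can stick in the up-state.

* **Medium** — method-of-lines FHN sheets (5-point Laplacian, Neumann or
  periodic edges, per-cell flux masks for internal tissue boundaries such as
  an annulus standing in for a vessel ostium), integrated with a fixed-step
  RK4 numba kernel validated against an adaptive reference.

* **Heterogeneity** — seeded generators for binary monostable/bistable
  mixtures and log-normal `b`-fields, plus annulus geometry with
  neighbor-count labeling of the rim cells.

* **Trials** — the Monte-Carlo repolarization-failure protocol (uniform
  pulse `I = 2` for 15 ms, failure = `V > 0` at 1000 ms) with
  boundary/midfield statistics, radial profiles and adjusted rates, and
  traveling-wave scenarios classified as normal propagation vs sustained
  ectopy.

* **Qu–Chung model** — a Luo–Rudy-variant biophysical ventricular cell
  (six ionic currents, Hodgkin–Huxley gating) in which slowing delayed-
  rectifier activation (`gamma`) or depolarizing the L-type calcium
  inactivation midpoint (`Delta`) produces ultra-long and bistable action
  potentials, in single cells and diffusively coupled sheets.

## Worked example

Bifurcation structure of the single cell:

```
$ ectopy bifurcation
SN at b = 1.640 (V = 0.625)
HB at b = 1.759 (V = 0.978)
```

Two unstable equilibria are born in a saddle-node at `b = 1.64`; the upper
one gains stability in a Hopf bifurcation at `b = 1.76`, so cells with
`b > 1.76` are bistable in isolation. The reduced model shifts this
threshold in coupled tissue:

```python
>>> from ectopy.continuation import hopf_curve, classify
>>> sm = hopf_curve(4)                 # 4 resting neighbors
>>> round(sm.c_at_b(3.0), 3)           # boundary coupling at b = 3
0.257
>>> classify(3.0, 0.30, 4), classify(3.0, 0.22, 4)
('monostable', 'bistable')
```

A cell with `b = 3` repolarizes when coupled to four resting neighbors at
`c = 0.3` but sticks in the up-state if coupling falls to `c = 0.22`.
The Monte-Carlo protocol quantifies the consequence in tissue with an
annulus (cells on the rim have only 2–3 neighbors):

```
$ ectopy trials --fraction 0.1 --b-bi 3.0 --c 0.22 --bc periodic --n-trials 300 --seed 1
boundary 10.31% (SE 0.22), midfield 3.46% (SE 0.04) -> trials.csv/.json
```

With 10% of cells bistable at `b = 3` and weak coupling, rim cells fail to
repolarize in about 10% of trials (that is, essentially every bistable cell
that lands on the rim) and midfield cells in about 3.5% (roughly a third of
the bistable cells there) — weak coupling plus missing neighbors turns the
tissue boundary into the preferred site of ectopy.

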