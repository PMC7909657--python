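"""Single-cell generalized FitzHugh-Nagumo dynamics.

The cell model is

    tau1 * dV/dt = V - V**3/3 - W + d + I
    tau2 * dW/dt = V + a - b*W

where ``V`` is the (dimensionless) membrane potential and ``W`` an abstract
recovery variable standing in for the repolarizing currents.  With the
default parameters (``a=1.25, d=0.6, tau1=10, tau2=400``) the nullclines
intersect near the left knee of the cubic at ``(V, W) = (-1.25, 0)``, which
makes the cell excitable.  The recovery decay rate ``b`` controls
repolarization: small ``b`` gives a monostable cell that always returns to
rest, large ``b`` creates a second stable equilibrium (the depolarized
"up-state") and the cell becomes bistable.

Time is measured in milliseconds throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "CellParams",
    "CellState",
    "Equilibrium",
    "StimulusPulse",
    "fhn_rhs",
    "nullclines",
    "jacobian",
    "find_equilibria",
    "resting_state",
    "simulate_cell",
    "solve_cubic",
]


@dataclass(frozen=True)
class CellParams:
    """Constants of one FitzHugh-Nagumo cell.

    Parameters
    ----------
    a : dimensionless offset of the linear (recovery) nullcline.
    b : decay rate of the recovery variable; must be positive.
    d : excitability offset of the cubic nullcline.
    tau1 : fast (membrane) time constant in ms.
    tau2 : slow (recovery) time constant in ms.
    I : injected current (dimensionless); additive inside dV/dt.
    """

    a: float = 1.25
    b: float = 1.0
    d: float = 0.6
    tau1: float = 10.0
    tau2: float = 400.0
    I: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tau1 > 0 and self.tau2 > 0):
            raise ValueError("time constants tau1, tau2 must be positive")
        if not self.b > 0:
            raise ValueError("recovery decay rate b must be positive")

    def with_b(self, b: float) -> "CellParams":
        return replace(self, b=b)


@dataclass(frozen=True)
class CellState:
    V: float
    W: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.V) and math.isfinite(self.W)):
            raise ValueError("cell state must be finite")


@dataclass(frozen=True)
class Equilibrium:
    state: CellState
    eigenvalues: tuple[complex, complex]
    stability: str  # "stable" | "unstable"

    @property
    def stable(self) -> bool:
        return self.stability == "stable"


@dataclass(frozen=True)
class StimulusPulse:
    """Square current pulse: ``I = amplitude`` for ``onset <= t < onset+duration``."""

    amplitude: float = 2.0
    onset: float = 0.0
    duration: float = 15.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")

    def __call__(self, t: float) -> float:
        on = (t >= self.onset) & (t < self.onset + self.duration)
        return self.amplitude * np.asarray(on, dtype=float)


def fhn_rhs(state: CellState, p: CellParams) -> tuple[float, float]:
    """Time derivatives (dV/dt, dW/dt) of the isolated cell."""
    V, W = state.V, state.W
    dV = (V - V**3 / 3.0 - W + p.d + p.I) / p.tau1
    dW = (V + p.a - p.b * W) / p.tau2
    return dV, dW


def nullclines(p: CellParams, V):
    """W-values of the cubic (dV/dt=0) and linear (dW/dt=0) nullclines at ``V``.

    Returns ``(W_cubic, W_linear)`` with
    ``W_cubic = V - V**3/3 + d + I`` and ``W_linear = (V + a)/b``.
    """
    V = np.asarray(V, dtype=float)
    w_cubic = V - V**3 / 3.0 + p.d + p.I
    w_linear = (V + p.a) / p.b
    return w_cubic, w_linear


def jacobian(V: float, p: CellParams) -> np.ndarray:
    """Jacobian of the cell equations at an equilibrium with potential ``V``."""
    return np.array(
        [
            [(1.0 - V * V) / p.tau1, -1.0 / p.tau1],
            [1.0 / p.tau2, -p.b / p.tau2],
        ]
    )


def solve_cubic(p_lin: float, q: float) -> np.ndarray:
    """Real roots of the depressed cubic ``x**3 + p_lin*x + q = 0``.

    Closed-form (Cardano / trigonometric) solution chosen by the sign of the
    discriminant, followed by one round of Newton polishing.  Returns roots
    in ascending order.
    """
    disc = -4.0 * p_lin**3 - 27.0 * q * q
    if disc > 0:  # three distinct real roots (requires p_lin < 0)
        m = 2.0 * math.sqrt(-p_lin / 3.0)
        theta = math.acos(np.clip(3.0 * q / (p_lin * m), -1.0, 1.0)) / 3.0
        roots = np.array([m * math.cos(theta - 2.0 * math.pi * k / 3.0) for k in range(3)])
    else:  # one real root
        half_q = q / 2.0
        rad = math.sqrt(max(half_q * half_q + (p_lin / 3.0) ** 3, 0.0))
        u = np.cbrt(-half_q + rad)
        v = np.cbrt(-half_q - rad)
        roots = np.array([u + v])
    # Newton polish to ~1e-12 residual
    for _ in range(3):
        f = roots**3 + p_lin * roots + q
        df = 3.0 * roots**2 + p_lin
        step = np.where(np.abs(df) > 1e-300, f / np.where(df == 0, 1.0, df), 0.0)
        roots = roots - step
    return np.sort(roots)


def equilibrium_potentials(p: CellParams) -> np.ndarray:
    """All real solutions V of ``V - V**3/3 - (V+a)/b + d + I = 0``, ascending."""
    # multiply by -3: V^3 - 3*(1 - 1/b)*V - 3*(d + I - a/b) = 0
    p_lin = -3.0 * (1.0 - 1.0 / p.b)
    q = -3.0 * (p.d + p.I - p.a / p.b)
    return solve_cubic(p_lin, q)


def _classify(eigs: np.ndarray) -> str:
    return "stable" if np.all(eigs.real < 0) else "unstable"


def find_equilibria(p: CellParams) -> list[Equilibrium]:
    """All equilibria of the isolated cell with eigenvalues and stability.

    The equilibrium potentials are the real roots of a cubic, so there are
    always one or three of them (counting multiplicity at a fold).  Results
    are ordered by increasing ``V``.
    """
    out = []
    for V in equilibrium_potentials(p):
        W = (V + p.a) / p.b
        eigs = np.linalg.eigvals(jacobian(V, p))
        out.append(Equilibrium(CellState(float(V), float(W)), tuple(eigs), _classify(eigs)))
    return out


def resting_state(p: CellParams) -> Equilibrium:
    """The lowest-V equilibrium (the resting membrane potential)."""
    return find_equilibria(p)[0]


def simulate_cell(
    p: CellParams,
    stim: StimulusPulse | None = None,
    t_end: float = 1000.0,
    y0: CellState | None = None,
    t_eval=None,
    rtol: float = 1e-6,
    atol: float = 1e-6,
):
    """Integrate one cell with an optional stimulus pulse.

    Uses an adaptive Runge-Kutta scheme (scipy ``RK45``) with 1e-6
    absolute/relative tolerances.  Returns the scipy solution object with
    ``sol.t`` in ms and ``sol.y = [V, W]``.
    """
    if y0 is None:
        y0 = resting_state(p).state

    def rhs(t, y):
        I = stim(t) if stim is not None else 0.0
        V, W = y
        return [
            (V - V**3 / 3.0 - W + p.d + p.I + I) / p.tau1,
            (V + p.a - p.b * W) / p.tau2,
        ]

    # restart integration at stimulus edges so the discontinuity is resolved
    edges = [0.0, t_end]
    if stim is not None:
        edges += [stim.onset, stim.onset + stim.duration]
    edges = sorted({e for e in edges if 0.0 <= e <= t_end})
    ts, ys = [], []
    y = [y0.V, y0.W]
    for t0, t1 in zip(edges[:-1], edges[1:]):
        seg_eval = None
        if t_eval is not None:
            te = np.asarray(t_eval, dtype=float)
            seg_eval = te[(te >= t0) & (te < t1)] if t1 < t_end else te[(te >= t0) & (te <= t1)]
        sol = solve_ivp(rhs, (t0, t1), y, method="RK45", rtol=rtol, atol=atol, t_eval=seg_eval, max_step=t1 - t0)
        if not sol.success:
            raise RuntimeError(f"cell integration failed at t={sol.t[-1]:.3f} ms")
        ts.append(sol.t)
        ys.append(sol.y)
        y = sol.y[:, -1] if sol.y.size else y
    t = np.concatenate(ts)
    yv = np.concatenate(ys, axis=1)
    return t, yv[0], yv[1]


def time_above(t: np.ndarray, V: np.ndarray, threshold: float = 0.0) -> float:
    """Total time the trace ``V(t)`` spends above ``threshold`` (trapezoidal count)."""
    above = V > threshold
    if not above.any():
        return 0.0
    return float(np.trapezoid(above.astype(float), t))
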