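"""Numerical continuation of FitzHugh-Nagumo equilibria.

Two analyses live here:

1. One-parameter continuation of the single-cell equilibria in the recovery
   decay rate ``b`` (pseudo-arclength predictor-corrector), with detection of
   the saddle-node (SN) where the linear nullcline becomes tangent to the
   cubic, and the Hopf bifurcation (HB) where the up-state gains stability.
   With default cell parameters the SN sits near b = 1.64 and the HB near
   b = 1.76; the up-state coexists stably with rest for b beyond the HB.

2. The *reduced model*: one cell of interest diffusively coupled to ``n``
   identical neighbors clamped at the resting potential ``Vr``,

       tau1 * dVo/dt = Vo - Vo**3/3 - Wo + d + n*c**2*(Vr - Vo)
       tau2 * dWo/dt = Vo + a - b*Wo.

   Following the Hopf point of the up-state in the (b, c) plane yields the
   stability boundary between configurations that always repolarize
   (monostable) and those whose up-state survives the repolarizing drain of
   the resting neighborhood (bistable).

Closed-form test functions (derivable from the cell equations):

* saddle-node:  1 - V**2 = 1/b        together with the equilibrium cubic,
* Hopf:         1 - V**2 - n*c**2 = b*tau1/tau2   (Jacobian trace zero),

with Jacobian determinant positive at a Hopf point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .cell import CellParams, CellState, Equilibrium, jacobian, solve_cubic

__all__ = [
    "BranchPoint",
    "ReducedParams",
    "StabilityMap",
    "continue_in_b",
    "find_bifurcations",
    "fold_b",
    "hopf_b",
    "reduced_equilibria",
    "classify",
    "hopf_curve",
]


# ---------------------------------------------------------------------------
# single-cell branch geometry
# ---------------------------------------------------------------------------

def _equilibrium_residual(V: float, b: float, p: CellParams) -> float:
    return V - V**3 / 3.0 - (V + p.a) / b + p.d + p.I


def _b_on_branch(V: float, p: CellParams) -> float:
    """Equilibrium manifold parametrized by V: b such that (V, b) is an equilibrium."""
    denom = V - V**3 / 3.0 + p.d + p.I
    return (V + p.a) / denom


def _det_test(V: float, b: float, p: CellParams) -> float:
    """Proportional to det(J); vanishes at a fold: 1 - b*(1 - V**2)."""
    return 1.0 - b * (1.0 - V * V)


def _trace_test(V: float, b: float, p: CellParams) -> float:
    """Jacobian trace; vanishes at a Hopf candidate."""
    return (1.0 - V * V) / p.tau1 - b / p.tau2


def fold_b(p: CellParams, v_bracket=(1e-3, 0.999)) -> tuple[float, float]:
    """Closed-form saddle-node location: solve 1 - V**2 = 1/b jointly with the cubic.

    Returns ``(b, V)`` of the fold on the upper branch.
    """
    g = lambda V: (1.0 - V * V) * _b_on_branch(V, p) - 1.0
    V = brentq(g, *v_bracket, xtol=1e-14)
    return _b_on_branch(V, p), V


def hopf_b(p: CellParams, v_bracket=(0.5, 0.999999)) -> tuple[float, float]:
    """Closed-form single-cell Hopf: solve 1 - V**2 = b*tau1/tau2 jointly with the cubic.

    Returns ``(b, V)`` of the Hopf point on the up-state branch.
    """
    g = lambda V: (1.0 - V * V) - _b_on_branch(V, p) * p.tau1 / p.tau2
    V = brentq(g, *v_bracket, xtol=1e-14)
    return _b_on_branch(V, p), V


# ---------------------------------------------------------------------------
# pseudo-arclength continuation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BranchPoint:
    b: float
    state: CellState
    eigenvalues: tuple[complex, complex]
    label: str = "regular"  # regular | SN | HB
    branch: int = 0

    @property
    def stable(self) -> bool:
        return all(ev.real < 0 for ev in self.eigenvalues)


def _make_point(V: float, b: float, p: CellParams, label="regular", branch=0) -> BranchPoint:
    W = (V + p.a) / b
    eigs = np.linalg.eigvals(jacobian(V, p.with_b(b)))
    return BranchPoint(float(b), CellState(float(V), float(W)), tuple(eigs), label, branch)


def _corrector(x: np.ndarray, tangent: np.ndarray, p: CellParams, tol: float, max_iter: int = 12):
    """Newton iteration on {F(V,b)=0, tangent.(x - x_pred)=0}; x = (V, b)."""
    x = x.copy()
    x_pred = x.copy()
    for _ in range(max_iter):
        V, b = x
        if b <= 0:
            return None
        F = _equilibrium_residual(V, b, p)
        G = tangent @ (x - x_pred)
        if abs(F) < tol and abs(G) < tol:
            return x
        J = np.array(
            [
                [1.0 - V * V - 1.0 / b, (V + p.a) / (b * b)],
                [tangent[0], tangent[1]],
            ]
        )
        try:
            dx = np.linalg.solve(J, np.array([F, G]))
        except np.linalg.LinAlgError:
            return None
        x = x - dx
        if not np.all(np.isfinite(x)):
            return None
    V, b = x
    if abs(_equilibrium_residual(V, b, p)) < tol:
        return x
    return None


def _branch_tangent(x: np.ndarray, p: CellParams, orient: np.ndarray) -> np.ndarray:
    V, b = x
    Fv = 1.0 - V * V - 1.0 / b
    Fb = (V + p.a) / (b * b)
    t = np.array([-Fb, Fv])
    t /= np.linalg.norm(t)
    if t @ orient < 0:
        t = -t
    return t


def _localize(V_lo: float, V_hi: float, p: CellParams, test, b_tol: float = 1e-3):
    """Bisect a test-function sign change along the branch (parametrized by V)."""
    f_lo = test(V_lo, _b_on_branch(V_lo, p), p)
    for _ in range(200):
        V_mid = 0.5 * (V_lo + V_hi)
        f_mid = test(V_mid, _b_on_branch(V_mid, p), p)
        if f_lo * f_mid <= 0:
            V_hi = V_mid
        else:
            V_lo, f_lo = V_mid, f_mid
        if (
            abs(_b_on_branch(V_lo, p) - _b_on_branch(V_hi, p)) < b_tol
            and abs(V_hi - V_lo) < 1e-10
        ):
            break
    V = 0.5 * (V_lo + V_hi)
    return V, _b_on_branch(V, p)


class BranchLossError(RuntimeError):
    """Corrector failed to converge; carries the last converged point."""

    def __init__(self, point: BranchPoint):
        self.last_point = point
        super().__init__(
            f"continuation lost the branch after (b={point.b:.6g}, V={point.state.V:.6g})"
        )


def _trace_branch(
    V0: float,
    b0: float,
    direction: float,
    p: CellParams,
    b_range: tuple[float, float],
    max_step: float,
    min_step: float,
    tol: float,
    branch_id: int,
) -> list[BranchPoint]:
    """Follow one connected equilibrium branch by pseudo-arclength from (V0, b0)."""
    b_lo, b_hi = b_range
    points = [_make_point(V0, b0, p, branch=branch_id)]
    x = np.array([V0, b0])
    tangent = _branch_tangent(x, p, orient=np.array([0.0, direction]))
    h = max_step
    n_fail = 0
    while True:
        x_new = _corrector(x + h * tangent, tangent, p, tol)
        if x_new is None:
            h *= 0.5
            n_fail += 1
            if h < min_step or n_fail > 40:
                raise BranchLossError(points[-1])
            continue
        n_fail = 0
        V_prev, b_prev = x
        V_new, b_new = x_new
        # bifurcation test functions between consecutive points
        for test, label in ((_det_test, "SN"), (_trace_test, "HB")):
            f0 = test(V_prev, b_prev, p)
            f1 = test(V_new, b_new, p)
            if f0 * f1 < 0:
                Vb, bb = _localize(V_prev, V_new, p, test)
                if label == "HB" and _det_test(Vb, bb, p) <= 0:
                    continue  # trace zero with det<0 is not a Hopf point
                if b_lo - 1e-9 <= bb <= b_hi + 1e-9:
                    points.append(_make_point(Vb, bb, p, label=label, branch=branch_id))
        new_tangent = (x_new - x) / np.linalg.norm(x_new - x)
        x, tangent = x_new, new_tangent
        h = min(h * 1.3, max_step)
        if not (b_lo - 1e-9 <= x[1] <= b_hi + 1e-9):
            # clamp the exit point onto the range boundary (natural continuation)
            b_edge = b_lo if x[1] < b_lo else b_hi
            g = lambda V: _equilibrium_residual(V, b_edge, p)
            try:
                V_edge = brentq(g, x[0] - 0.5, x[0] + 0.5, xtol=1e-12)
                points.append(_make_point(V_edge, b_edge, p, branch=branch_id))
            except ValueError:
                points.append(_make_point(x[0], x[1], p, branch=branch_id))
            break
        points.append(_make_point(x[0], x[1], p, branch=branch_id))
        if abs(x[0]) > 5.0 or len(points) > 20000:
            break
    return points


def continue_in_b(
    p: CellParams | None = None,
    b_range: tuple[float, float] = (0.5, 3.0),
    max_step: float = 0.1,
    min_step: float = 0.01,
    tol: float = 1e-6,
) -> list[BranchPoint]:
    """Track all equilibrium branches of the single cell over ``b_range``.

    Pseudo-arclength predictor-corrector with secant predictor.  Saddle-node
    and Hopf points are localized to |db| < 1e-3 by bisection on the
    determinant and trace test functions and inserted into the returned list
    with labels ``"SN"`` / ``"HB"``.
    """
    p = p or CellParams()
    b_lo, b_hi = b_range
    if not (0.0 < b_lo < b_hi <= 10.0):
        raise ValueError("b_range must satisfy 0 < b_lo < b_hi <= 10")

    from .cell import equilibrium_potentials

    points: list[BranchPoint] = []
    # resting branch: seed at the low end, march right
    roots_lo = equilibrium_potentials(p.with_b(b_lo))
    points += _trace_branch(float(roots_lo[0]), b_lo, +1.0, p, b_range, max_step, min_step, tol, 0)
    # upper/middle branch: seed at the high end (if it exists), march left
    roots_hi = equilibrium_potentials(p.with_b(b_hi))
    if len(roots_hi) == 3:
        points += _trace_branch(float(roots_hi[-1]), b_hi, -1.0, p, b_range, max_step, min_step, tol, 1)
    return points


def find_bifurcations(points: list[BranchPoint]) -> dict[str, list[BranchPoint]]:
    """Group the labeled bifurcation points of a continuation run."""
    out: dict[str, list[BranchPoint]] = {"SN": [], "HB": []}
    for pt in points:
        if pt.label in out:
            out[pt.label].append(pt)
    return out


# ---------------------------------------------------------------------------
# reduced model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReducedParams:
    """A cell of interest coupled to ``n`` neighbors clamped at rest ``Vr``."""

    cell: CellParams = field(default_factory=CellParams)
    n: int = 4
    c: float = 0.3
    Vr: float = -1.25

    def __post_init__(self) -> None:
        if self.n < 0 or self.n != int(self.n):
            raise ValueError("neighbor count n must be a non-negative integer")
        if self.c < 0:
            raise ValueError("coupling strength c must be non-negative")


def reduced_jacobian(V: float, rp: ReducedParams) -> np.ndarray:
    p = rp.cell
    nc2 = rp.n * rp.c**2
    return np.array(
        [
            [(1.0 - V * V - nc2) / p.tau1, -1.0 / p.tau1],
            [1.0 / p.tau2, -p.b / p.tau2],
        ]
    )


def reduced_equilibria(rp: ReducedParams) -> list[Equilibrium]:
    """Equilibria of the reduced model with eigenvalues and stability labels."""
    p = rp.cell
    nc2 = rp.n * rp.c**2
    # -3x: V^3 - 3(1 - 1/b - nc2) V - 3(d + I - a/b + nc2*Vr) = 0
    p_lin = -3.0 * (1.0 - 1.0 / p.b - nc2)
    q = -3.0 * (p.d + p.I - p.a / p.b + nc2 * rp.Vr)
    out = []
    for V in solve_cubic(p_lin, q):
        W = (V + p.a) / p.b
        eigs = np.linalg.eigvals(reduced_jacobian(float(V), rp))
        stab = "stable" if np.all(eigs.real < 0) else "unstable"
        out.append(Equilibrium(CellState(float(V), float(W)), tuple(eigs), stab))
    return out


def classify(b: float, c: float, n: int, cell: CellParams | None = None) -> str:
    """Operating regime of the reduced model: ``"monostable"`` or ``"bistable"``.

    Bistable means a stable up-state coexists with the stable resting state,
    i.e. the reduced model has at least two stable equilibria.
    """
    cell = (cell or CellParams()).with_b(b)
    rp = ReducedParams(cell=cell, n=n, c=c)
    n_stable = sum(e.stable for e in reduced_equilibria(rp))
    return "bistable" if n_stable >= 2 else "monostable"


@dataclass(frozen=True)
class StabilityMap:
    """Hopf curve of the reduced model in the (b, c) plane for ``n`` neighbors.

    The curve is single-valued as c(b) over the scanned range; configurations
    below it (weaker coupling) are bistable, those above are monostable.
    """

    n: int
    b: np.ndarray
    c: np.ndarray
    cell: CellParams = field(default_factory=CellParams)

    def c_at_b(self, b: float) -> float:
        """Coupling strength on the stability boundary at recovery rate ``b``."""
        return float(np.interp(b, self.b, self.c))

    def b_at_c(self, c: float) -> float:
        """Recovery rate at which the boundary crosses coupling strength ``c``."""
        if not (self.c.min() <= c <= self.c.max()):
            raise ValueError(f"c={c} outside the computed boundary range")
        idx = np.argsort(self.c)
        return float(np.interp(c, self.c[idx], self.b[idx]))

    def classify(self, b: float, c: float) -> str:
        """Regime of configuration (b, c); bistable lies below the boundary."""
        if self.n == 0:
            return "bistable" if b >= self.b[0] else "monostable"
        if b < self.b[0]:
            return "monostable"
        return "bistable" if c < self.c_at_b(b) else "monostable"

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.b, self.c]), delimiter=",", header="b,c", comments="")


def _hopf_upstate(b: float, n: int, cell: CellParams, Vr: float, v_guess: float | None):
    """Up-state Hopf point of the reduced model at fixed b.

    Eliminating Wo and substituting the trace condition
    ``n*c**2 = 1 - Vo**2 - b*tau1/tau2`` into the equilibrium equation leaves
    one cubic in Vo; the up-state root is the largest one with positive
    coupling.  Returns ``(Vo, c)`` or None when no admissible root exists.
    """
    p = cell
    k = b * p.tau1 / p.tau2
    # (2/3)Vo^3 - Vr Vo^2 + (k - 1/b) Vo + (d + I - a/b + Vr(1 - k)) = 0
    A = -1.5 * Vr
    B = 1.5 * (k - 1.0 / b)
    C = 1.5 * (p.d + p.I - p.a / b + Vr * (1.0 - k))
    # depressed form via Vo = t - A/3
    p_lin = B - A * A / 3.0
    q = 2.0 * A**3 / 27.0 - A * B / 3.0 + C
    roots = solve_cubic(p_lin, q) - A / 3.0
    cands = []
    for Vo in roots:
        s = 1.0 - Vo * Vo - k  # = n c^2
        if s <= 0:
            continue
        det_tf = 1.0 - b * (1.0 - Vo * Vo - s)  # det > 0 required for a Hopf
        if det_tf <= 0:
            continue
        cands.append((float(Vo), float(np.sqrt(s / n))))
    if not cands:
        return None
    if v_guess is not None:
        return min(cands, key=lambda vc: abs(vc[0] - v_guess))
    return max(cands, key=lambda vc: vc[0])


def hopf_curve(
    n: int,
    b_range: tuple[float, float] = (1.77, 6.0),
    step: float = 0.05,
    cell: CellParams | None = None,
    Vr: float = -1.25,
) -> StabilityMap:
    """Follow the up-state Hopf point of the reduced model through (b, c).

    The curve is seeded at the single-cell Hopf (where c -> 0) and continued
    toward larger ``b`` in steps of at most 0.1, tracking the up-state root
    between consecutive points.  For ``n = 0`` the cell decouples and the
    boundary degenerates to a vertical line at the single-cell Hopf value.
    """
    if step > 0.1:
        raise ValueError("adjacent-point spacing in b must be <= 0.1")
    cell = cell or CellParams()
    b_hb, V_hb = hopf_b(cell)
    if n == 0:
        bs = np.array([b_hb, b_hb])
        return StabilityMap(n=0, b=bs, c=np.array([0.0, np.inf]), cell=cell)
    b_lo = max(b_range[0], b_hb)
    bs = np.unique(np.concatenate([[b_hb], np.arange(b_lo, b_range[1] + step / 2, step)]))
    out_b, out_c = [], []
    v_guess = V_hb
    for b in bs:
        res = _hopf_upstate(float(b), n, cell, Vr, v_guess)
        if res is None:
            continue
        Vo, c = res
        v_guess = Vo
        out_b.append(float(b))
        out_c.append(c)
    if out_b and out_b[0] > b_hb:  # curve is seeded at the single-cell Hopf, where c -> 0
        out_b.insert(0, b_hb)
        out_c.insert(0, 0.0)
    return StabilityMap(n=n, b=np.asarray(out_b), c=np.asarray(out_c), cell=cell)
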