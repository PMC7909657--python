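"""2-D reaction-diffusion simulation of the heterogeneous FitzHugh-Nagumo sheet.

The sheet is the method-of-lines discretization of

    tau1 * dV/dt = V - V**3/3 - W + c**2 * (Vxx + Vyy) + d + I
    tau2 * dW/dt = V + a - b*W

on a regular grid (dx = dy = 1) with a 5-point Laplacian.  Neumann (no-flux)
domain edges are closed by mirror substitution; periodic edges wrap.  A
per-cell, per-direction flux mask implements internal tissue boundaries
(e.g. an annulus): a masked direction contributes the cell's own value in
place of the neighbor, which zeroes the flux across that edge.

Two integrators are provided: a fixed-step RK4 numba kernel (the default,
for Monte-Carlo throughput) and an adaptive solver (scipy, 1e-6 tolerances)
used as the accuracy reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels
from .cell import CellParams
from .heterogeneity import DIRECTIONS, _OFFSETS, AnnulusGeometry, _shift

__all__ = [
    "MediumConfig",
    "FieldState",
    "StimulusProtocol",
    "laplacian",
    "integrate",
    "detect_failures",
    "resting_field",
]


@dataclass(frozen=True)
class StimulusProtocol:
    """Square current pulse applied to part of the sheet.

    ``support`` is ``"uniform"`` (all tissue cells), ``"left"`` (the first
    ``left_cols`` grid columns) or an explicit boolean mask.
    """

    amplitude: float = 2.0
    onset: float = 0.0
    duration: float = 15.0
    support: object = "uniform"
    left_cols: int = 1

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")

    def field(self, cfg: "MediumConfig") -> np.ndarray:
        """Per-cell current amplitude while the pulse is on."""
        amp = np.zeros(cfg.shape)
        if isinstance(self.support, str):
            if self.support == "uniform":
                amp[:, :] = self.amplitude
            elif self.support == "left":
                amp[:, : self.left_cols] = self.amplitude
            else:
                raise ValueError(f"unknown stimulus support {self.support!r}")
        else:
            amp[np.asarray(self.support, dtype=bool)] = self.amplitude
        amp[cfg.absent] = 0.0
        return amp


@dataclass(frozen=True)
class MediumConfig:
    """Grid geometry, coupling, heterogeneity and boundary handling."""

    b_field: np.ndarray
    c: float = 1.0
    bc: str = "neumann"  # neumann | periodic
    dx: float = 1.0
    dy: float = 1.0
    cell: CellParams = field(default_factory=CellParams)
    flux_mask: np.ndarray | None = None  # (4, rows, cols) bool, True = receives flux
    annulus: AnnulusGeometry | None = None

    def __post_init__(self) -> None:
        b = np.ascontiguousarray(np.asarray(self.b_field, dtype=float))
        object.__setattr__(self, "b_field", b)
        if b.ndim != 2 or b.shape[0] < 2 or b.shape[1] < 2:
            raise ValueError("grid shape must be at least (2, 2)")
        if np.any(b <= 0):
            raise ValueError("all b values must be positive")
        if self.c < 0:
            raise ValueError("coupling strength c must be non-negative")
        if self.bc not in ("neumann", "periodic"):
            raise ValueError("bc must be 'neumann' or 'periodic'")
        mask = self.flux_mask
        if mask is None and self.annulus is not None:
            mask = self.annulus.flux_mask
        if mask is None:
            mask = np.ones((4,) + b.shape, dtype=bool)
        mask = np.ascontiguousarray(np.asarray(mask, dtype=bool))
        if mask.shape != (4,) + b.shape:
            raise ValueError("flux_mask must have shape (4, rows, cols)")
        object.__setattr__(self, "flux_mask", mask)
        self._check_mask_symmetry()

    @property
    def shape(self) -> tuple[int, int]:
        return self.b_field.shape

    @property
    def absent(self) -> np.ndarray:
        """Cells outside the tissue (fully masked annulus interior)."""
        if self.annulus is not None:
            return self.annulus.absent
        return ~self.flux_mask.any(axis=0)

    @property
    def tissue(self) -> np.ndarray:
        return ~self.absent

    def _check_mask_symmetry(self) -> None:
        opposite = {"N": "S", "S": "N", "E": "W", "W": "E"}
        for k, name in enumerate(DIRECTIONS):
            dr, dc = _OFFSETS[name]
            ko = DIRECTIONS.index(opposite[name])
            neighbor_recv = _shift(self.flux_mask[ko], dr, dc, self.bc)
            if not np.array_equal(self.flux_mask[k], neighbor_recv):
                raise ValueError("flux mask is not symmetric across shared edges")

    @classmethod
    def homogeneous(cls, shape, b: float = 1.0, c: float = 1.0, **kw) -> "MediumConfig":
        return cls(b_field=np.full(shape, float(b)), c=c, **kw)


@dataclass
class FieldState:
    V: np.ndarray
    W: np.ndarray
    t: float = 0.0

    def copy(self) -> "FieldState":
        return FieldState(self.V.copy(), self.W.copy(), self.t)


def resting_field(cfg: MediumConfig, exact: bool = True) -> FieldState:
    """Initial condition at rest.

    With ``exact=True`` every cell is placed on its own single-cell resting
    equilibrium (vectorized Newton on the equilibrium cubic, seeded at the
    nominal rest V = -1.25); otherwise the nominal uniform rest (V = -1.25,
    W = 0) is used.
    """
    p = cfg.cell
    if not exact:
        return FieldState(np.full(cfg.shape, -1.25), np.zeros(cfg.shape), 0.0)
    b = cfg.b_field
    V = np.full(cfg.shape, -1.25)
    for _ in range(60):
        F = V - V**3 / 3.0 - (V + p.a) / b + p.d + p.I
        dF = 1.0 - V * V - 1.0 / b
        V = V - F / dF
        if np.max(np.abs(F)) < 1e-14:
            break
    W = (V + p.a) / b
    return FieldState(V, W, 0.0)


def laplacian(V: np.ndarray, cfg: MediumConfig) -> np.ndarray:
    """Masked 5-point Laplacian of ``V`` (numpy reference implementation)."""
    V = np.asarray(V, dtype=float)
    if V.shape != cfg.shape:
        raise ValueError(f"field shape {V.shape} does not match grid {cfg.shape}")
    terms = np.zeros_like(V)
    for k, name in enumerate(DIRECTIONS):
        dr, dc = _OFFSETS[name]
        vnb = _shift(V, dr, dc, cfg.bc)
        vnb = np.where(cfg.flux_mask[k], vnb, V)
        h2 = cfg.dy**2 if name in ("N", "S") else cfg.dx**2
        terms += (vnb - V) / h2
    return terms


def _rhs_numpy(V, W, cfg: MediumConfig, stim_field):
    p = cfg.cell
    dV = (V - V**3 / 3.0 - W + p.d + p.I + cfg.c**2 * laplacian(V, cfg) + stim_field) / p.tau1
    dW = (V + p.a - cfg.b_field * W) / p.tau2
    absent = cfg.absent
    dV[absent] = 0.0
    dW[absent] = 0.0
    return dV, dW


class IntegrationDivergedError(RuntimeError):
    def __init__(self, t: float):
        self.t = t
        super().__init__(f"non-finite field state at t = {t:.1f} ms")


def _segments(t0, t_end, stim: StimulusProtocol | None, snapshot_times):
    """Break [t0, t_end] at stimulus edges and snapshot times."""
    cuts = {t0, t_end}
    if stim is not None:
        for e in (stim.onset, stim.onset + stim.duration):
            if t0 < e < t_end:
                cuts.add(e)
    for ts in snapshot_times:
        if t0 < ts < t_end:
            cuts.add(float(ts))
    return sorted(cuts)


def integrate(
    state: FieldState,
    cfg: MediumConfig,
    stim: StimulusProtocol | None = None,
    t_end: float = 1000.0,
    dt: float = 0.1,
    method: str = "rk4",
    snapshot_times=None,
) -> tuple[FieldState, list[FieldState]]:
    """Integrate the sheet from ``state.t`` to ``t_end``.

    ``method="rk4"`` uses the fixed-step numba kernel with step ``dt``
    (adjusted per segment so stimulus edges and snapshot times are hit
    exactly); ``method="adaptive"`` uses scipy RK45 at 1e-6 abs/rel
    tolerance.  Returns the final state and the list of snapshots taken at
    ``snapshot_times``.  Raises :class:`IntegrationDivergedError` if the
    state becomes non-finite.
    """
    snapshot_times = sorted(snapshot_times) if snapshot_times is not None else []
    state = state.copy()
    snaps: list[FieldState] = []
    edges = _segments(state.t, t_end, stim, snapshot_times)
    snap_set = {round(t, 9) for t in snapshot_times}
    for t0, t1 in zip(edges[:-1], edges[1:]):
        amp = np.zeros(cfg.shape)
        if stim is not None and stim.onset <= t0 < stim.onset + stim.duration:
            amp = stim.field(cfg)
        if method == "rk4":
            n = max(1, int(round((t1 - t0) / dt)))
            dt_seg = (t1 - t0) / n
            _kernels.fhn_rk4(
                state.V, state.W, cfg.b_field, cfg.flux_mask,
                np.ascontiguousarray(cfg.tissue), cfg.c**2,
                cfg.cell.a, cfg.cell.d, cfg.cell.tau1, cfg.cell.tau2,
                cfg.bc == "periodic", amp, dt_seg, n,
            )
        elif method == "adaptive":
            shape = cfg.shape
            ncell = shape[0] * shape[1]

            def rhs(t, y):
                V = y[:ncell].reshape(shape)
                W = y[ncell:].reshape(shape)
                dV, dW = _rhs_numpy(V, W, cfg, amp)
                return np.concatenate([dV.ravel(), dW.ravel()])

            sol = solve_ivp(rhs, (t0, t1), np.concatenate([state.V.ravel(), state.W.ravel()]),
                            method="RK45", rtol=1e-6, atol=1e-6)
            if not sol.success:
                raise IntegrationDivergedError(sol.t[-1])
            state.V = sol.y[:ncell, -1].reshape(shape)
            state.W = sol.y[ncell:, -1].reshape(shape)
        else:
            raise ValueError(f"unknown method {method!r}")
        state.t = t1
        if not (np.all(np.isfinite(state.V)) and np.all(np.isfinite(state.W))):
            raise IntegrationDivergedError(t1)
        if round(t1, 9) in snap_set or (t1 == t_end and t_end in snapshot_times):
            snaps.append(state.copy())
    return state, snaps


def detect_failures(state: FieldState, cfg: MediumConfig, threshold: float = 0.0) -> np.ndarray:
    """Boolean grid of tissue cells still depolarized (V > threshold)."""
    return (state.V > threshold) & cfg.tissue
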