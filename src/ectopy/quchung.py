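"""Luo-Rudy-variant ventricular action-potential model (Qu-Chung form).

The membrane equation (capacitance normalized to 1 uF/cm^2, so currents are
in uA/uF, voltage in mV, time in ms) is

    dV/dt = I_stim - (I_Na + I_CaL + I_K + I_K1 + I_Kp + I_b)

with Hodgkin-Huxley gates m, h, j (fast sodium), d, f (L-type calcium) and
x (delayed rectifier), each obeying ``tau_y dy/dt = y_inf - y``.  The rate
constants of m, h, j and x, the inward-rectifier steady state K1_inf, the
plateau gate Kp and the Xi factor of I_K follow the 1991 Luo-Rudy phase-1
formulation; two modifications create bistable (non-repolarizing) action
potentials:

* ``gamma`` scales tau_x, slowing delayed-rectifier activation (rate 1/gamma);
* the L-type steady states are replaced by sigmoids
  ``d_inf = 1/(1 + exp(-(V + V0)/alpha))`` and
  ``f_inf = 1/(1 + exp((V + V0 + Delta)/beta))``,
  so a negative ``Delta`` moves the inactivation midpoint to more
  depolarized voltages, widening the I_CaL window current.

Sign convention for f_inf: f is an inactivation gate and must close with
depolarization, so the exponent carries a positive sign (the gate is
decreasing in V).  With ``gamma = 4, Delta = -15`` the isolated cell fails
to repolarize, which is the behavior this convention is required to produce.

Intracellular calcium follows ``d[Ca]i/dt = -1e-4*I_CaL + 0.07*(1e-4 - [Ca]i)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import _kernels

__all__ = [
    "QuChungParams",
    "QuChungState",
    "gate_kinetics",
    "currents",
    "resting_state",
    "simulate_cell",
    "simulate_sheet",
    "apd90",
]

GATES = ("m", "h", "j", "d", "f", "x")


@dataclass(frozen=True)
class QuChungParams:
    """All model constants; defaults are the published parameter set
    (with the reduced inward-rectifier conductance I_K1,max = 0.3)."""

    Ko: float = 5.4      # extracellular K+ (mM)
    Ki: float = 145.0    # intracellular K+ (mM)
    Nao: float = 140.0   # extracellular Na+ (mM)
    Nai: float = 10.0    # intracellular Na+ (mM)
    Cao: float = 1.8     # extracellular Ca++ (mM)
    R: float = 8.314
    T: float = 310.0
    F: float = 96.5
    PNaK: float = 0.0183
    g_CaL: float = 0.09
    g_Kp: float = 0.0183
    g_b: float = 0.0392
    g_Na: float = 16.0
    g_K1: float = 0.3
    g_K: float = 0.282
    gamma: float = 1.0   # tau_x scaling (activation rate 1/gamma)
    alpha: float = 9.4   # d_inf slope (mV)
    beta: float = 7.2    # f_inf slope (mV)
    delta: float = 0.0   # f_inf shift (mV)
    V0: float = 24.5     # center of the I_CaL activation window (mV)
    stim_amplitude: float = 80.0  # uA/uF
    stim_duration: float = 0.5    # ms

    def __post_init__(self) -> None:
        for name in ("Ko", "Ki", "Nao", "Nai", "Cao", "R", "T", "F"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @property
    def RTF(self) -> float:
        return self.R * self.T / self.F

    @property
    def ENa(self) -> float:
        return self.RTF * np.log(self.Nao / self.Nai)

    @property
    def EK(self) -> float:
        return self.RTF * np.log((self.Ko + self.PNaK * self.Nao) / (self.Ki + self.PNaK * self.Nai))

    @property
    def EK1(self) -> float:
        return self.RTF * np.log(self.Ko / self.Ki)

    @property
    def EKp(self) -> float:
        return self.EK1

    def ECaL(self, cai) -> float:
        return 7.7 - 13.0287 * np.log(np.asarray(cai) / self.Cao)

    def bistable(self, gamma: float = 4.0, delta: float = -15.0) -> "QuChungParams":
        return replace(self, gamma=gamma, delta=delta)


@dataclass
class QuChungState:
    V: float
    m: float
    h: float
    j: float
    d: float
    f: float
    x: float
    cai: float

    def __post_init__(self) -> None:
        if self.cai <= 0:
            raise ValueError("intracellular calcium must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.m, self.h, self.j, self.d, self.f, self.x, self.cai])

    @classmethod
    def from_array(cls, y) -> "QuChungState":
        return cls(*[float(v) for v in y])


# ---------------------------------------------------------------------------
# Luo-Rudy rate constants (1991 phase-1 formulation), vectorized in V
# ---------------------------------------------------------------------------

def _lr1_rates(V, p: QuChungParams):
    V = np.asarray(V, dtype=float)
    am = 0.32 * (V + 47.13) / (1.0 - np.exp(-0.1 * (V + 47.13)))
    bm = 0.08 * np.exp(-V / 11.0)

    lo = V < -40.0
    ah = np.where(lo, 0.135 * np.exp((80.0 + V) / -6.8), 0.0)
    bh = np.where(
        lo,
        3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V),
        1.0 / (0.13 * (1.0 + np.exp((V + 10.66) / -11.1))),
    )
    with np.errstate(over="ignore"):
        aj = np.where(
            lo,
            (-1.2714e5 * np.exp(0.2444 * V) - 3.474e-5 * np.exp(-0.04391 * V))
            * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))),
            0.0,
        )
    bj = np.where(
        lo,
        0.1212 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14))),
        0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0))),
    )

    ad = 0.095 * np.exp(-0.01 * (V - 5.0)) / (1.0 + np.exp(-0.072 * (V - 5.0)))
    bd = 0.07 * np.exp(-0.017 * (V + 44.0)) / (1.0 + np.exp(0.05 * (V + 44.0)))
    af = 0.012 * np.exp(-0.008 * (V + 28.0)) / (1.0 + np.exp(0.15 * (V + 28.0)))
    bf = 0.0065 * np.exp(-0.02 * (V + 30.0)) / (1.0 + np.exp(-0.2 * (V + 30.0)))

    ax = 0.0005 * np.exp(0.083 * (V + 50.0)) / (1.0 + np.exp(0.057 * (V + 50.0)))
    bx = 0.0013 * np.exp(-0.06 * (V + 20.0)) / (1.0 + np.exp(-0.04 * (V + 20.0)))
    return {"m": (am, bm), "h": (ah, bh), "j": (aj, bj), "d": (ad, bd), "f": (af, bf), "x": (ax, bx)}


def xi_factor(V):
    """Outward-rectification factor Xi of I_K."""
    V = np.asarray(V, dtype=float)
    num = np.exp(0.04 * (V + 77.0)) - 1.0
    den = (V + 77.0) * np.exp(0.04 * (V + 35.0))
    near = np.abs(V + 77.0) < 1e-6
    safe_den = np.where(near, 1.0, den)
    xi = 2.837 * np.where(near, 0.04 / np.exp(0.04 * (-77.0 + 35.0)), num / safe_den)
    return np.where(V > -100.0, xi, 1.0)


def k1_inf(V, p: QuChungParams):
    dv = np.asarray(V, dtype=float) - p.EK1
    a = 1.02 / (1.0 + np.exp(0.2385 * (dv - 59.215)))
    b = (0.49124 * np.exp(0.08032 * (dv + 5.476)) + np.exp(0.06175 * (dv - 594.31))) / (
        1.0 + np.exp(-0.5143 * (dv + 4.753))
    )
    return a / (a + b)


def kp_gate(V):
    return 1.0 / (1.0 + np.exp((7.488 - np.asarray(V, dtype=float)) / 5.98))


def gate_kinetics(V, p: QuChungParams) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Steady state and time constant ``(y_inf, tau_y)`` for every gate at ``V``.

    tau_x is scaled by ``gamma``; the d and f steady states are the modified
    sigmoids (see module docstring), their time constants are retained from
    the Luo-Rudy rates.
    """
    rates = _lr1_rates(V, p)
    out = {}
    for g, (a, b) in rates.items():
        tau = 1.0 / (a + b)
        yinf = a * tau
        if g == "x":
            tau = tau * p.gamma
        out[g] = (yinf, tau)
    V = np.asarray(V, dtype=float)
    d_inf = 1.0 / (1.0 + np.exp(-(V + p.V0) / p.alpha))
    f_inf = 1.0 / (1.0 + np.exp((V + p.V0 + p.delta) / p.beta))
    out["d"] = (d_inf, out["d"][1])
    out["f"] = (f_inf, out["f"][1])
    return out


def currents(state: QuChungState, p: QuChungParams) -> dict[str, float]:
    """The six membrane currents and the reversal potentials at one state."""
    if state.cai <= 0:
        raise ValueError("non-physical intracellular calcium")
    V = state.V
    ena, ek, ek1 = p.ENa, p.EK, p.EK1
    ecal = float(p.ECaL(state.cai))
    out = {
        "I_Na": p.g_Na * state.m**3 * state.h * state.j * (V - ena),
        "I_CaL": p.g_CaL * state.d * state.f * (V - ecal),
        "I_K": p.g_K * float(xi_factor(V)) * state.x * (V - ek),
        "I_K1": p.g_K1 * (p.Ko / 5.4) * float(k1_inf(V, p)) * (V - ek1),
        "I_Kp": p.g_Kp * float(kp_gate(V)) * (V - p.EKp),
        "I_b": p.g_b * (V + 59.87),
        "E_Na": ena,
        "E_CaL": ecal,
        "E_K": ek,
        "E_K1": ek1,
        "E_Kp": p.EKp,
    }
    return out


def _rhs(t, y, p: QuChungParams, stim_amp, stim_until):
    V, m, h, j, d, f, x, cai = y
    cai = max(cai, 1e-12)
    st = QuChungState(V, m, h, j, d, f, x, cai)
    cur = currents(st, p)
    i_ion = cur["I_Na"] + cur["I_CaL"] + cur["I_K"] + cur["I_K1"] + cur["I_Kp"] + cur["I_b"]
    i_stim = stim_amp if t < stim_until else 0.0
    kin = gate_kinetics(V, p)
    dy = [i_stim - i_ion]
    for g, val in zip(GATES, (m, h, j, d, f, x)):
        yinf, tau = kin[g]
        dy.append((float(yinf) - val) / float(tau))
    dy.append(-0.0001 * cur["I_CaL"] + 0.07 * (0.0001 - cai))
    return dy


def resting_state(p: QuChungParams) -> QuChungState:
    """Quiescent equilibrium: gates at steady state, calcium balanced."""
    cai = 1e-4
    V = -84.0
    for _ in range(8):
        def f0(v):
            kin = gate_kinetics(v, p)
            st = QuChungState(v, *[float(kin[g][0]) for g in GATES], cai)
            cur = currents(st, p)
            return -(cur["I_Na"] + cur["I_CaL"] + cur["I_K"] + cur["I_K1"] + cur["I_Kp"] + cur["I_b"])
        V = brentq(f0, -95.0, -50.0, xtol=1e-10)
        kin = gate_kinetics(V, p)
        st = QuChungState(V, *[float(kin[g][0]) for g in GATES], cai)
        ical = currents(st, p)["I_CaL"]
        cai_new = 1e-4 - (1e-4 / 0.07) * ical
        if abs(cai_new - cai) < 1e-12:
            cai = cai_new
            break
        cai = cai_new
    kin = gate_kinetics(V, p)
    return QuChungState(V, *[float(kin[g][0]) for g in GATES], cai)


@dataclass
class CellTrace:
    t: np.ndarray
    V: np.ndarray
    y: np.ndarray
    apd90: float | None
    repolarized: bool


def apd90(t: np.ndarray, V: np.ndarray, onset: float = 0.0):
    """Action-potential duration at 90% repolarization.

    The repolarization level is ``V_rest + 0.1 * (V_peak - V_rest)`` with
    the pre-stimulus baseline as V_rest.  Returns ``(apd, repolarized)``;
    ``apd`` is measured from ``onset`` to the last sample at or above the
    level, and ``repolarized`` is False if the trace ends still above it.
    """
    pre = V[t <= onset]
    v_rest = float(pre[-1]) if pre.size else float(V[0])
    v_peak = float(V.max())
    level = v_rest + 0.1 * (v_peak - v_rest)
    above = V >= level
    if not above.any():
        return 0.0, True
    last = np.where(above)[0][-1]
    repol = not above[-1]
    return float(t[last] - onset), repol


def simulate_cell(
    p: QuChungParams,
    t_end: float = 10000.0,
    stim_amplitude: float | None = None,
    stim_duration: float | None = None,
    y0: QuChungState | None = None,
    n_eval: int = 4000,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> CellTrace:
    """Integrate one cell through a stimulus at t = 0 (adaptive LSODA)."""
    amp = p.stim_amplitude if stim_amplitude is None else stim_amplitude
    dur = p.stim_duration if stim_duration is None else stim_duration
    if y0 is None:
        y0 = resting_state(p)
    t_eval = np.linspace(0.0, t_end, n_eval)
    ys, ts = [], []
    ycur = y0.as_array()
    for (t0, t1, a) in ((0.0, dur, amp), (dur, t_end, 0.0)):
        if t1 <= t0:
            continue
        seg = np.unique(np.concatenate([t_eval[(t_eval >= t0) & (t_eval <= t1)], [t0, t1]]))
        sol = solve_ivp(
            _rhs, (t0, t1), ycur, args=(p, a, t1 if a else 0.0),
            method="LSODA", rtol=rtol, atol=atol, t_eval=seg, max_step=5.0,
        )
        if not sol.success:
            raise RuntimeError(f"cell integration failed at t={sol.t[-1]:.2f} ms")
        ts.append(sol.t)
        ys.append(sol.y)
        ycur = sol.y[:, -1]
    t = np.concatenate(ts)
    y = np.concatenate(ys, axis=1)
    dur_apd, repol = apd90(t, y[0], onset=0.0)
    return CellTrace(t=t, V=y[0], y=y, apd90=dur_apd if repol else None, repolarized=repol)


# ---------------------------------------------------------------------------
# 2-D sheet
# ---------------------------------------------------------------------------

_TAB_VMIN, _TAB_VMAX, _TAB_N = -120.0, 120.0, 4801


def _build_tables(p_mono: QuChungParams, p_bi: QuChungParams, dt: float):
    Vg = np.linspace(_TAB_VMIN, _TAB_VMAX, _TAB_N)
    inf_tabs, edt_tabs = {}, {}
    for g in GATES:
        inf_tabs[g] = np.empty((2, _TAB_N))
        edt_tabs[g] = np.empty((2, _TAB_N))
    for ct, p in enumerate((p_mono, p_bi)):
        kin = gate_kinetics(Vg, p)
        for g in GATES:
            yinf, tau = kin[g]
            inf_tabs[g][ct] = yinf
            edt_tabs[g][ct] = np.exp(-dt / tau)
    return Vg, inf_tabs, edt_tabs


@dataclass
class SheetResult:
    outcome: str
    times: np.ndarray
    depolarized_counts: np.ndarray
    final_V: np.ndarray
    snapshots: list[tuple[float, np.ndarray]]
    bistable_mask: np.ndarray


def simulate_sheet(
    bistable_mask: np.ndarray,
    c: float = 0.15,
    p_mono: QuChungParams | None = None,
    p_bi: QuChungParams | None = None,
    t_end: float = 10000.0,
    dt: float = 0.02,
    stim_amplitude: float | None = None,
    stim_duration: float | None = None,
    stim_cols: int = 1,
    sample_every: float = 20.0,
    snapshot_times=(),
    depol_threshold: float = -40.0,
) -> SheetResult:
    """Simulate a sheet of ventricular cells with diffusive coupling ``c**2``.

    ``bistable_mask`` selects the cells carrying the bistable parameter set
    (by default ``gamma = 4, Delta = -15``); the rest are monostable.  Cells
    in the left-hand ``stim_cols`` columns are stimulated briefly at t = 0 to
    launch a rightward wave.  Boundaries are Neumann (no-flux).  Gates use
    Rush-Larsen exponential updates on tabulated kinetics; V and [Ca]i use
    forward Euler.  The run is classified by whether any cell remains
    depolarized (V > ``depol_threshold``) at ``t_end``.
    """
    p_mono = p_mono or QuChungParams()
    p_bi = p_bi or p_mono.bistable()
    mask = np.asarray(bistable_mask, dtype=bool)
    rows, cols = mask.shape
    amp = p_mono.stim_amplitude if stim_amplitude is None else stim_amplitude
    dur = p_mono.stim_duration if stim_duration is None else stim_duration

    rest = resting_state(p_mono)
    V = np.full((rows, cols), rest.V)
    gates = {g: np.full((rows, cols), getattr(rest, g if g != "j" else "j")) for g in GATES}
    cai = np.full((rows, cols), rest.cai)
    ctype = mask.astype(np.uint8)
    # bistable cells start on their own resting gates (identical except f/x)
    rest_bi = resting_state(p_bi)
    V[mask] = rest_bi.V
    for g in GATES:
        gates[g][mask] = getattr(rest_bi, g)
    cai[mask] = rest_bi.cai

    Vg, inf_tabs, edt_tabs = _build_tables(p_mono, p_bi, dt)
    xi_t = xi_factor(Vg)
    k1_t = k1_inf(Vg, p_mono)
    kp_t = kp_gate(Vg)
    dv_inv = (_TAB_N - 1) / (_TAB_VMAX - _TAB_VMIN)

    stim_field = np.zeros((rows, cols))
    stim_field[:, :stim_cols] = amp

    sample_times = list(np.arange(sample_every, t_end + sample_every / 2, sample_every))
    edges = sorted({0.0, dur, t_end} | {t for t in sample_times if 0 < t < t_end}
                   | {float(t) for t in snapshot_times if 0 < t < t_end})
    times, counts, snaps = [], [], []
    snapshot_set = {round(float(t), 9) for t in snapshot_times}
    t = 0.0
    for t0, t1 in zip(edges[:-1], edges[1:]):
        n = max(1, int(round((t1 - t0) / dt)))
        dt_seg = (t1 - t0) / n
        stim_now = stim_field if t0 < dur else np.zeros((rows, cols))
        _kernels.qc_sheet_step(
            V, gates["m"], gates["h"], gates["j"], gates["d"], gates["f"], gates["x"], cai,
            ctype, c * c, dt_seg, n,
            _TAB_VMIN, dv_inv, _TAB_N,
            inf_tabs["m"], inf_tabs["h"], inf_tabs["j"], inf_tabs["d"], inf_tabs["f"], inf_tabs["x"],
            edt_tabs["m"], edt_tabs["h"], edt_tabs["j"], edt_tabs["d"], edt_tabs["f"], edt_tabs["x"],
            xi_t, k1_t, kp_t,
            p_mono.g_Na, p_mono.g_CaL, p_mono.g_K, p_mono.g_K1 * (p_mono.Ko / 5.4), p_mono.g_Kp, p_mono.g_b,
            p_mono.ENa, p_mono.EK, p_mono.EK1, p_mono.Cao,
            stim_now, False,
        )
        t = t1
        if not np.all(np.isfinite(V)):
            raise RuntimeError(f"sheet integration diverged at t = {t:.1f} ms")
        if t in sample_times or t == t_end:
            times.append(t)
            counts.append(int((V > depol_threshold).sum()))
        if round(t, 9) in snapshot_set:
            snaps.append((t, V.copy()))
    outcome = "sustained ectopy" if (V > depol_threshold).any() else "normal propagation"
    return SheetResult(outcome, np.array(times), np.array(counts), V.copy(), snaps, mask)
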