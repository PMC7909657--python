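"""Numba kernels for fixed-step tissue integration.

The FitzHugh-Nagumo sheet uses classical RK4; the biophysical sheet uses
Rush-Larsen exponential updates for the Hodgkin-Huxley gates (tabulated
voltage-dependent functions) with forward-Euler membrane/calcium updates.
Both kernels implement the masked 5-point Laplacian: an out-of-grid neighbor
under Neumann closure, or a masked direction, contributes the cell's own
value, which zeroes the corresponding flux.
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _fhn_rhs(V, W, b, recv, active, c2, a, d, tau1, tau2, periodic, stim, dV, dW):
    rows, cols = V.shape
    for i in range(rows):
        for j in range(cols):
            if not active[i, j]:  # absent tissue: frozen
                dV[i, j] = 0.0
                dW[i, j] = 0.0
                continue
            v = V[i, j]
            # neighbor values; mirror substitution at Neumann edges,
            # self-substitution for masked directions (no-flux)
            if recv[0, i, j]:  # N: row-1
                ii = i - 1 if i > 0 else (rows - 1 if periodic else i)
                vn = V[ii, j]
            else:
                vn = v
            if recv[1, i, j]:  # S: row+1
                ii = i + 1 if i < rows - 1 else (0 if periodic else i)
                vs = V[ii, j]
            else:
                vs = v
            if recv[2, i, j]:  # E: col+1
                jj = j + 1 if j < cols - 1 else (0 if periodic else j)
                ve = V[i, jj]
            else:
                ve = v
            if recv[3, i, j]:  # W: col-1
                jj = j - 1 if j > 0 else (cols - 1 if periodic else j)
                vw = V[i, jj]
            else:
                vw = v
            lap = (ve - 2.0 * v + vw) + (vn - 2.0 * v + vs)
            dV[i, j] = (v - v * v * v / 3.0 - W[i, j] + d + c2 * lap + stim[i, j]) / tau1
            dW[i, j] = (v + a - b[i, j] * W[i, j]) / tau2


@njit(cache=True, fastmath=True)
def fhn_rk4(V, W, b, recv, active, c2, a, d, tau1, tau2, periodic, stim, dt, n_steps):
    """Advance the sheet in place by ``n_steps`` RK4 steps of size ``dt``."""
    rows, cols = V.shape
    k1V = np.empty((rows, cols))
    k1W = np.empty((rows, cols))
    k2V = np.empty((rows, cols))
    k2W = np.empty((rows, cols))
    k3V = np.empty((rows, cols))
    k3W = np.empty((rows, cols))
    k4V = np.empty((rows, cols))
    k4W = np.empty((rows, cols))
    Vt = np.empty((rows, cols))
    Wt = np.empty((rows, cols))
    for _ in range(n_steps):
        _fhn_rhs(V, W, b, recv, active, c2, a, d, tau1, tau2, periodic, stim, k1V, k1W)
        for i in range(rows):
            for j in range(cols):
                Vt[i, j] = V[i, j] + 0.5 * dt * k1V[i, j]
                Wt[i, j] = W[i, j] + 0.5 * dt * k1W[i, j]
        _fhn_rhs(Vt, Wt, b, recv, active, c2, a, d, tau1, tau2, periodic, stim, k2V, k2W)
        for i in range(rows):
            for j in range(cols):
                Vt[i, j] = V[i, j] + 0.5 * dt * k2V[i, j]
                Wt[i, j] = W[i, j] + 0.5 * dt * k2W[i, j]
        _fhn_rhs(Vt, Wt, b, recv, active, c2, a, d, tau1, tau2, periodic, stim, k3V, k3W)
        for i in range(rows):
            for j in range(cols):
                Vt[i, j] = V[i, j] + dt * k3V[i, j]
                Wt[i, j] = W[i, j] + dt * k3W[i, j]
        _fhn_rhs(Vt, Wt, b, recv, active, c2, a, d, tau1, tau2, periodic, stim, k4V, k4W)
        for i in range(rows):
            for j in range(cols):
                V[i, j] += dt / 6.0 * (k1V[i, j] + 2.0 * k2V[i, j] + 2.0 * k3V[i, j] + k4V[i, j])
                W[i, j] += dt / 6.0 * (k1W[i, j] + 2.0 * k2W[i, j] + 2.0 * k3W[i, j] + k4W[i, j])


@njit(cache=True, fastmath=True, inline="always")
def _interp(table, ct, idx, frac):
    return table[ct, idx] * (1.0 - frac) + table[ct, idx + 1] * frac


@njit(cache=True, fastmath=True)
def qc_sheet_step(
    V, m, h, j_, d, f, x, cai, ctype,
    c2, dt, n_steps,
    vmin, dv_inv, ntab,
    minf, hinf, jinf, dinf, finf, xinf,
    medt, hedt, jedt, dedt, fedt, xedt,
    xi_t, k1inf_t, kp_t,
    gNa, gCaL, gK, gK1r, gKp, gb,
    ENa, EK, EK1, cao,
    stim, periodic,
):
    """Advance the biophysical sheet in place by ``n_steps`` of size ``dt`` ms.

    Gate tables have shape (2, ntab): row 0 for monostable cells, row 1 for
    bistable cells (which differ in the f-gate steady state and the x-gate
    time constant).  ``xi_t``, ``k1inf_t`` and ``kp_t`` are shared 1-D tables.
    """
    rows, cols = V.shape
    dVdt = np.empty((rows, cols))
    for _ in range(n_steps):
        for i in range(rows):
            for j in range(cols):
                v = V[i, j]
                ii = i - 1 if i > 0 else (rows - 1 if periodic else i)
                vn = V[ii, j]
                ii = i + 1 if i < rows - 1 else (0 if periodic else i)
                vs = V[ii, j]
                jj = j + 1 if j < cols - 1 else (0 if periodic else j)
                ve = V[i, jj]
                jj = j - 1 if j > 0 else (cols - 1 if periodic else j)
                vw = V[i, jj]
                lap = (ve - 2.0 * v + vw) + (vn - 2.0 * v + vs)

                # table lookup index for this voltage
                u = (v - vmin) * dv_inv
                if u < 0.0:
                    u = 0.0
                elif u > ntab - 2:
                    u = float(ntab - 2)
                idx = int(u)
                frac = u - idx
                ct = ctype[i, j]

                ecal = 7.7 - 13.0287 * np.log(cai[i, j] / cao)
                ina = gNa * m[i, j] ** 3 * h[i, j] * j_[i, j] * (v - ENa)
                ical = gCaL * d[i, j] * f[i, j] * (v - ecal)
                xi = xi_t[idx] * (1.0 - frac) + xi_t[idx + 1] * frac
                ik = gK * xi * x[i, j] * (v - EK)
                k1inf = k1inf_t[idx] * (1.0 - frac) + k1inf_t[idx + 1] * frac
                ik1 = gK1r * k1inf * (v - EK1)
                kp = kp_t[idx] * (1.0 - frac) + kp_t[idx + 1] * frac
                ikp = gKp * kp * (v - EK1)
                ib = gb * (v + 59.87)
                dVdt[i, j] = stim[i, j] + c2 * lap - (ina + ical + ik + ik1 + ikp + ib)

                # Rush-Larsen gate updates (exact for frozen rates over dt)
                yi = _interp(minf, ct, idx, frac)
                m[i, j] = yi + (m[i, j] - yi) * _interp(medt, ct, idx, frac)
                yi = _interp(hinf, ct, idx, frac)
                h[i, j] = yi + (h[i, j] - yi) * _interp(hedt, ct, idx, frac)
                yi = _interp(jinf, ct, idx, frac)
                j_[i, j] = yi + (j_[i, j] - yi) * _interp(jedt, ct, idx, frac)
                yi = _interp(dinf, ct, idx, frac)
                d[i, j] = yi + (d[i, j] - yi) * _interp(dedt, ct, idx, frac)
                yi = _interp(finf, ct, idx, frac)
                f[i, j] = yi + (f[i, j] - yi) * _interp(fedt, ct, idx, frac)
                yi = _interp(xinf, ct, idx, frac)
                x[i, j] = yi + (x[i, j] - yi) * _interp(xedt, ct, idx, frac)
                cai[i, j] += dt * (-0.0001 * ical + 0.07 * (0.0001 - cai[i, j]))
        for i in range(rows):
            for j in range(cols):
                V[i, j] += dt * dVdt[i, j]
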