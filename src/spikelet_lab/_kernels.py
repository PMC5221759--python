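"""Numba inner loop of the compartmental integrator.

The scheme is the implicit trapezoid (Crank-Nicolson) on the branched cable
with staggered gating updates, solved per step by ordered (Hines)
elimination on the tree.  Compartments are ordered parents-before-children,
so one backward elimination sweep and one forward substitution solve the
symmetric quasi-tridiagonal system exactly.

Units: mV, ms, nA, uS, nF (so g*V is nA and C*dV/dt is nA).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_simulation"]


@njit(cache=True, inline="always")
def _safe_linoid(x, q):
    if abs(x / q) < 1e-7:
        return q + 0.5 * x
    return x / (1.0 - np.exp(-x / q))


@njit(cache=True, inline="always")
def _gates(model_id, p, v, vna):
    """Return (minf, mtau, hinf, htau, ninf, ntau) for one compartment.

    ``vna`` is the voltage seen by the (possibly shifted) sodium gates.
    """
    if model_id == 0:
        # generic alpha/beta table: 6 x (kind, a, th, q)
        out = np.empty(6)
        for i in range(6):
            kind = int(p[4 * i])
            a = p[4 * i + 1]
            th = p[4 * i + 2]
            q = p[4 * i + 3]
            vv = vna if i < 4 else v
            if kind == 0:
                r = a * _safe_linoid(vv - th, q)
            elif kind == 1:
                r = a * _safe_linoid(th - vv, q)
            elif kind == 2:
                r = a * np.exp(-(vv - th) / q)
            else:
                r = a / (1.0 + np.exp(-(vv - th) / q))
            out[i] = r
        am, bm, ah, bh, an, bn = out[0], out[1], out[2], out[3], out[4], out[5]
        return (
            am / (am + bm), 1.0 / (am + bm),
            ah / (ah + bh), 1.0 / (ah + bh),
            an / (an + bn), 1.0 / (an + bn),
        )
    # na3/kdr formulation
    tha, qa, Ra, Rb = p[0], p[1], p[2], p[3]
    thi1, thi2, qd, qg, Rd, Rg = p[4], p[5], p[6], p[7], p[8], p[9]
    thinf, qinf, mmin, hmin, qt_na = p[10], p[11], p[12], p[13], p[14]
    vhalf, zeta, gm, a0, nmin, qt_k, cfac = (
        p[15], p[16], p[17], p[18], p[19], p[20], p[21],
    )
    am = Ra * _safe_linoid(vna - tha, qa)
    bm = Rb * _safe_linoid(tha - vna, qa)
    mtau = 1.0 / (am + bm) / qt_na
    if mtau < mmin:
        mtau = mmin
    minf = am / (am + bm)
    ah = Rd * _safe_linoid(vna - thi1, qd)
    bh = Rg * _safe_linoid(thi2 - vna, qg)
    htau = 1.0 / (ah + bh) / qt_na
    if htau < hmin:
        htau = hmin
    hinf = 1.0 / (1.0 + np.exp((vna - thinf) / qinf))
    alp = np.exp(zeta * cfac * (v - vhalf))
    bet = np.exp(zeta * gm * cfac * (v - vhalf))
    ninf = 1.0 / (1.0 + alp)
    ntau = bet / (qt_k * a0 * (1.0 + alp))
    if ntau < nmin:
        ntau = nmin
    return minf, mtau, hinf, htau, ninf, ntau


@njit(cache=True)
def run_simulation(
    parent,        # (n,) int64, parent index in Hines order, -1 for root
    g_par,         # (n,) float64, axial conductance to parent (uS)
    C,             # (n,) float64, membrane capacitance (nF)
    gL,            # (n,) float64, leak conductance (uS)
    eL,            # (n,) float64, leak reversal (mV)
    gNa,           # (n,) float64 (uS)
    gK,            # (n,) float64 (uS)
    vshift_na,     # (n,) float64, shift of Na curves (mV, negative = hyperpol.)
    h_tau_fixed,   # (n,) float64, fixed inactivation tau in ms; nan = dynamic
    E_Na, E_K,     # floats (mV)
    model_id,      # int64 kinetics family
    kin_params,    # (np,) float64 kinetics constants
    n_exp,         # int64 power of the K activation gate
    inj_comp,      # (ki,) int64
    inj_I,         # (ki, nsteps+1) float64 (nA)
    cond_comp,     # (kc,) int64
    cond_E,        # (kc,) float64 (mV)
    cond_g,        # (kc, nsteps+1) float64 (uS)
    clamp_comp,    # (kv,) int64
    clamp_V,       # (kv, nsteps+1) float64 (mV), nan = clamp inactive
    dt, nsteps,
    v_init,        # float64 (mV)
    rec_idx,       # (nr,) int64 compartments whose V is recorded
    rec_state_idx, # (ns,) int64
    rec_state_var, # (ns,) int64 0=m 1=h 2=n
):
    n = parent.shape[0]
    V = np.full(n, v_init)
    m = np.empty(n)
    h = np.empty(n)
    ng = np.empty(n)
    for i in range(n):
        minf, _, hinf, _, ninf, _ = _gates(
            model_id, kin_params, v_init, v_init - vshift_na[i]
        )
        m[i] = minf
        h[i] = hinf
        ng[i] = ninf

    nr = rec_idx.shape[0]
    ns = rec_state_idx.shape[0]
    kv = clamp_comp.shape[0]
    out_V = np.empty((nr, nsteps + 1))
    out_S = np.empty((ns, nsteps + 1))
    out_Icl = np.zeros((kv, nsteps + 1))
    for r in range(nr):
        out_V[r, 0] = V[rec_idx[r]]
    for s in range(ns):
        var = rec_state_var[s]
        i = rec_state_idx[s]
        out_S[s, 0] = m[i] if var == 0 else (h[i] if var == 1 else ng[i])

    d = np.empty(n)
    rhs = np.empty(n)
    Gtot = np.empty(n)
    sumGE = np.empty(n)
    clamped = np.zeros(n, dtype=np.bool_)
    clamp_val = np.zeros(n)

    for j in range(nsteps):
        # ---- gating update (exponential, staggered) ----
        for i in range(n):
            if gNa[i] > 0.0 or gK[i] > 0.0:
                minf, mtau, hinf, htau, ninf, ntau = _gates(
                    model_id, kin_params, V[i], V[i] - vshift_na[i]
                )
                m[i] += (1.0 - np.exp(-dt / mtau)) * (minf - m[i])
                if not np.isnan(h_tau_fixed[i]):
                    htau = h_tau_fixed[i]
                h[i] += (1.0 - np.exp(-dt / htau)) * (hinf - h[i])
                ng[i] += (1.0 - np.exp(-dt / ntau)) * (ninf - ng[i])

        # ---- membrane conductances and source terms ----
        for i in range(n):
            gna = gNa[i] * m[i] * m[i] * m[i] * h[i]
            if n_exp == 1:
                gk = gK[i] * ng[i]
            else:
                gk = gK[i] * ng[i] * ng[i] * ng[i] * ng[i]
            Gtot[i] = gna + gk + gL[i]
            sumGE[i] = gna * E_Na + gk * E_K + gL[i] * eL[i]
        for k in range(cond_comp.shape[0]):
            i = cond_comp[k]
            gmid = 0.5 * (cond_g[k, j] + cond_g[k, j + 1])
            Gtot[i] += gmid
            sumGE[i] += gmid * cond_E[k]

        # ---- assemble trapezoid system ----
        for i in range(n):
            d[i] = C[i] / dt + 0.5 * Gtot[i]
            rhs[i] = (C[i] / dt - 0.5 * Gtot[i]) * V[i] + sumGE[i]
        for k in range(inj_comp.shape[0]):
            i = inj_comp[k]
            rhs[i] += 0.5 * (inj_I[k, j] + inj_I[k, j + 1])
        for i in range(1, n):
            p = parent[i]
            g = 0.5 * g_par[i]
            d[i] += g
            d[p] += g
            dv = V[p] - V[i]
            rhs[i] += g * dv
            rhs[p] -= g * dv

        # ---- voltage clamps: fix rows, move couplings to RHS ----
        any_clamp = False
        for k in range(kv):
            if not np.isnan(clamp_V[k, j + 1]):
                any_clamp = True
        if kv > 0:
            for i in range(n):
                clamped[i] = False
            for k in range(kv):
                vc = clamp_V[k, j + 1]
                if not np.isnan(vc):
                    i = clamp_comp[k]
                    clamped[i] = True
                    clamp_val[i] = vc
            if any_clamp:
                for i in range(1, n):
                    p = parent[i]
                    g = 0.5 * g_par[i]
                    if clamped[i] and not clamped[p]:
                        rhs[p] += g * clamp_val[i]
                    elif clamped[p] and not clamped[i]:
                        rhs[i] += g * clamp_val[p]

        # ---- Hines elimination (children are after parents) ----
        for i in range(n - 1, 0, -1):
            if clamped[i]:
                continue
            p = parent[i]
            if clamped[p]:
                continue
            g = 0.5 * g_par[i]
            f = g / d[i]
            d[p] -= g * f
            rhs[p] += f * rhs[i]
        Vnew = np.empty(n)
        if clamped[0]:
            Vnew[0] = clamp_val[0]
        else:
            Vnew[0] = rhs[0] / d[0]
        for i in range(1, n):
            if clamped[i]:
                Vnew[i] = clamp_val[i]
            else:
                p = parent[i]
                if clamped[p]:
                    Vnew[i] = rhs[i] / d[i]
                else:
                    Vnew[i] = (rhs[i] + 0.5 * g_par[i] * Vnew[p]) / d[i]

        # ---- clamp currents (electrode current holding the command) ----
        for k in range(kv):
            vc = clamp_V[k, j + 1]
            if np.isnan(vc):
                continue
            i = clamp_comp[k]
            vmid = 0.5 * (V[i] + Vnew[i])
            icl = C[i] * (Vnew[i] - V[i]) / dt + Gtot[i] * vmid - sumGE[i]
            for c in range(1, n):
                if c == i:
                    p = parent[c]
                    icl -= g_par[c] * (0.5 * (V[p] + Vnew[p]) - vmid)
                elif parent[c] == i:
                    icl -= g_par[c] * (0.5 * (V[c] + Vnew[c]) - vmid)
            for kk in range(inj_comp.shape[0]):
                if inj_comp[kk] == i:
                    icl -= 0.5 * (inj_I[kk, j] + inj_I[kk, j + 1])
            out_Icl[k, j + 1] = icl

        V = Vnew
        for r in range(nr):
            out_V[r, j + 1] = V[rec_idx[r]]
        for s in range(ns):
            var = rec_state_var[s]
            i = rec_state_idx[s]
            out_S[s, j + 1] = m[i] if var == 0 else (h[i] if var == 1 else ng[i])
        if not np.isfinite(V[0]):
            return out_V, out_S, out_Icl, (j + 1) * dt
    return out_V, out_S, out_Icl, -1.0
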