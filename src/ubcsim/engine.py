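"""Fixed-step integration engine for single-compartment UBC models.

Gates and the membrane potential use exponential-Euler updates; the
AMPA Markov scheme uses an implicit (backward-Euler) update that
conserves total occupancy to machine precision; the mGluR2 cascade
uses exact exponential updates of its two linear ODEs.  The engine is
compiled with numba; all state is packed into flat float64 arrays.

Units: mV, ms, S/cm², µF/cm², pA.  Point currents (injected, bias,
synaptic) are converted to densities through the membrane area.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .params import AMPAParams, CellParams, MGluR2Params

__all__ = [
    "pack_cell", "pack_ampa", "pack_mglur2", "integrate",
    "IntegrationError", "REC_NONE", "REC_AMPA", "REC_MGLUR2",
    "membrane_area_um2",
]

REC_NONE, REC_AMPA, REC_MGLUR2 = 0, 1, 2

# indices into the packed cell vector
_N_CELL = 43


class IntegrationError(RuntimeError):
    """Numerical failure (NaN/Inf state) during integration."""


def membrane_area_um2(diameter_um: float) -> float:
    """Membrane area of the single compartment in µm².

    Uses the cylinder-of-length-equal-to-diameter convention (area
    π·d², no end caps), the common single-compartment convention.
    """
    if not diameter_um > 0:
        raise ValueError(f"diameter must be > 0, got {diameter_um}")
    return math.pi * diameter_um**2


def _kp(c, key, default=0.0):
    return float(c.kinetic_params.get(key, default))


def pack_cell(p: CellParams) -> np.ndarray:
    """Pack a CellParams into the flat vector the kernel consumes."""
    area_cm2 = membrane_area_um2(p.diameter) * 1e-8
    v = np.zeros(_N_CELL)
    v[0] = area_cm2
    v[1] = p.specific_capacitance
    by_name = {c.name: c for c in p.conductances}
    na = by_name.get("Na")
    k = by_name.get("K")
    ks = by_name.get("K_slow")
    h = by_name.get("H")
    pas = by_name.get("pas")
    for idx, c in ((2, na), (4, k), (6, ks), (8, h), (10, pas)):
        if c is not None:
            v[idx] = c.gmax
            v[idx + 1] = c.erev
    v[12] = p.bias_pA
    if na is not None:
        v[13:19] = [_kp(na, "m_vhalf"), _kp(na, "m_k", 1.0), _kp(na, "m_t0", 0.05),
                    _kp(na, "m_ta"), _kp(na, "m_tv"), _kp(na, "m_tw", 1.0)]
        v[19:25] = [_kp(na, "h_vhalf"), _kp(na, "h_k", -1.0), _kp(na, "h_t0", 1.0),
                    _kp(na, "h_ta"), _kp(na, "h_tv"), _kp(na, "h_tw", 1.0)]
    if k is not None:
        v[25:31] = [_kp(k, "n_vhalf"), _kp(k, "n_k", 1.0), _kp(k, "n_t0", 1.0),
                    _kp(k, "n_ta"), _kp(k, "n_tv"), _kp(k, "n_tw", 1.0)]
    if ks is not None:
        v[31:37] = [_kp(ks, "s_vhalf"), _kp(ks, "s_k", 1.0), _kp(ks, "s_t0", 50.0),
                    _kp(ks, "s_ta"), _kp(ks, "s_tv"), _kp(ks, "s_tw", 1.0)]
    if h is not None:
        v[37:43] = [_kp(h, "q_vhalf"), _kp(h, "q_k", -1.0), _kp(h, "q_t0", 200.0),
                    _kp(h, "q_ta"), _kp(h, "q_tv"), _kp(h, "q_tw", 1.0)]
    return v


def pack_ampa(p: AMPAParams) -> np.ndarray:
    return np.array([p.kb, p.ku, p.kd, p.krs, p.kc, p.hill_bind, p.gmax_nS,
                     p.erev])


def pack_mglur2(p: MGluR2Params) -> np.ndarray:
    return np.array([p.k1, p.k2, p.k3, p.k4, p.kd, p.hill_n,
                     p.gmax_nS, p.erev, p.hill_bind])


def initial_gates(p: CellParams) -> np.ndarray:
    """Steady-state gate values at v_init (m, h, n, s, q)."""
    cv = pack_cell(p)
    g = np.zeros(5)
    v = p.v_init
    g[0] = _sigmoid_py(v, cv[13], cv[14])
    g[1] = _sigmoid_py(v, cv[19], cv[20])
    g[2] = _sigmoid_py(v, cv[25], cv[26])
    g[3] = _sigmoid_py(v, cv[31], cv[32])
    g[4] = _sigmoid_py(v, cv[37], cv[38])
    return g


def _sigmoid_py(v, vh, k):
    if k == 0:
        return 1.0
    return 1.0 / (1.0 + math.exp(-(v - vh) / k))


@njit(cache=True, inline="always")
def _xinf(v, vh, k):
    return 1.0 / (1.0 + np.exp(-(v - vh) / k))


@njit(cache=True, inline="always")
def _xtau(v, t0, ta, tv, tw):
    if ta == 0.0:
        return t0
    z = (v - tv) / tw
    return t0 + ta * np.exp(-z * z)


@njit(cache=True)
def _kernel(v0, gates, rec, cell, recvec, rec_kind, glu, i_inj, dt,
            vm_out, isyn_out):
    """Integrate one cell.  Returns -1 on success, else the index of the
    first non-finite state."""
    n = glu.shape[0]
    area = cell[0]
    cm = cell[1]
    gna = cell[2]; ena = cell[3]
    gk = cell[4]; ek = cell[5]
    gks = cell[6]; eks = cell[7]
    gh = cell[8]; eh = cell[9]
    gpas = cell[10]; epas = cell[11]
    bias = cell[12]

    m = gates[0]; h = gates[1]; ng = gates[2]; s = gates[3]; q = gates[4]

    v = v0
    for i in range(n):
        vm_out[i] = v
        T = glu[i]

        # synaptic current (outward positive), pA
        isyn = 0.0
        if rec_kind == 1:
            isyn = recvec[6] * (rec[1] + rec[3]) * (v - recvec[7])
        elif rec_kind == 2:
            gp = rec[1] ** recvec[5]
            isyn = recvec[6] * gp / (gp + recvec[4]) * (v - recvec[7])
        isyn_out[i] = isyn

        # gate updates (exponential Euler at voltage v)
        if gna > 0.0:
            mi = _xinf(v, cell[13], cell[14])
            mt = _xtau(v, cell[15], cell[16], cell[17], cell[18])
            m = mi + (m - mi) * np.exp(-dt / mt)
            hi = _xinf(v, cell[19], cell[20])
            ht = _xtau(v, cell[21], cell[22], cell[23], cell[24])
            h = hi + (h - hi) * np.exp(-dt / ht)
        if gk > 0.0:
            ni = _xinf(v, cell[25], cell[26])
            nt = _xtau(v, cell[27], cell[28], cell[29], cell[30])
            ng = ni + (ng - ni) * np.exp(-dt / nt)
        if gks > 0.0:
            si = _xinf(v, cell[31], cell[32])
            st = _xtau(v, cell[33], cell[34], cell[35], cell[36])
            s = si + (s - si) * np.exp(-dt / st)
        if gh > 0.0:
            qi = _xinf(v, cell[37], cell[38])
            qt = _xtau(v, cell[39], cell[40], cell[41], cell[42])
            q = qi + (q - qi) * np.exp(-dt / qt)

        # receptor updates
        if rec_kind == 1:
            # backward-Euler on the cyclic scheme C⇄O→D→S→C
            kb = recvec[0]; ku = recvec[1]; kdr = recvec[2]
            krs = recvec[3]; kc = recvec[4]
            a = kb * T ** recvec[5] if T > 0.0 else 0.0
            al = 1.0 + dt * (ku + kdr)
            be = 1.0 + dt * krs
            ga = 1.0 + dt * kc
            pO = rec[1] / al
            qO = dt * a / al
            pD = (rec[2] + dt * kdr * pO) / be
            qD = dt * kdr * qO / be
            pS = (rec[3] + dt * krs * pD) / ga
            qS = dt * krs * qD / ga
            cNew = (rec[0] + dt * ku * pO + dt * kc * pS) / (
                1.0 + dt * a - dt * ku * qO - dt * kc * qS)
            rec[0] = cNew
            rec[1] = pO + qO * cNew
            rec[2] = pD + qD * cNew
            rec[3] = pS + qS * cNew
        elif rec_kind == 2:
            k1 = recvec[0]; k2 = recvec[1]; k3 = recvec[2]; k4 = recvec[3]
            arate = k1 * T ** recvec[8] if T > 0.0 else 0.0
            tot = arate + k2
            if tot > 0.0:
                rinf = arate / tot
                rec[0] = rinf + (rec[0] - rinf) * np.exp(-dt * tot)
            if k4 > 0.0:
                ginf = k3 * rec[0] / k4
                rec[1] = ginf + (rec[1] - ginf) * np.exp(-dt * k4)
            else:
                rec[1] = rec[1] + dt * k3 * rec[0]

        # membrane update (exponential Euler)
        m3h = m * m * m * h
        n4 = ng * ng * ng * ng
        gsum = gna * m3h + gk * n4 + gks * s + gh * q + gpas
        gesum = (gna * m3h * ena + gk * n4 * ek + gks * s * eks +
                 gh * q * eh + gpas * epas)
        ipoint = (i_inj[i] + bias - isyn) * 1e-9 / area  # mA/cm²
        bcoef = 1000.0 * gsum / cm
        if bcoef > 0.0:
            vinf = (1000.0 * (gesum + ipoint)) / (cm * bcoef)
            v = vinf + (v - vinf) * np.exp(-dt * bcoef)
        else:
            v = v + dt * 1000.0 * ipoint / cm
        if not np.isfinite(v):
            return i
    gates[0] = m; gates[1] = h; gates[2] = ng; gates[3] = s; gates[4] = q
    return -1


def integrate(cell_vec, v0, gates, rec_state, rec_kind, recvec, glu,
              i_inj_pA, dt, t_offset_ms=0.0):
    """Run the kernel over ``len(glu)`` steps.

    Mutates ``gates`` and ``rec_state`` in place (final state) and
    returns (vm, i_syn_pA).  Raises :class:`IntegrationError` naming the
    first offending time if the state becomes non-finite.
    """
    n = len(glu)
    vm = np.empty(n)
    isyn = np.empty(n)
    if recvec is None:
        recvec = np.zeros(8)
    if rec_state is None:
        rec_state = np.zeros(4)
    bad = _kernel(v0, gates, rec_state, cell_vec, recvec, rec_kind,
                  np.asarray(glu, dtype=float),
                  np.asarray(i_inj_pA, dtype=float), dt, vm, isyn)
    if bad >= 0:
        raise IntegrationError(
            f"non-finite membrane state at t = {t_offset_ms + bad * dt:.3f} ms"
        )
    return vm, isyn
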