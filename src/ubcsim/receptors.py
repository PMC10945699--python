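"""Receptor kinetic schemes: AMPA Markov chain and mGluR2 cascade.

These are the reference (pure-Python) implementations of the per-step
updates used by the integration engine; they are numerically identical
to the compiled kernel (same implicit/exponential updates at the same
dt), which is asserted by the test suite.

AMPA scheme (ON UBC): a cyclic four-state chain

    C --kb·T--> O --kd--> D --krs--> S --kc--> C,   O --ku--> C

with two conducting states, O (fast EPSC) and S (slow rebound EPSC).
Sustained glutamate piles occupancy into D and S; when transmission
stops, the slowly closing S state carries the prolonged rebound current
that drives the ON UBC's burst.

mGluR2 cascade (OFF UBC): bound-receptor fraction R and activated
G protein G,

    dR/dt = k1·T·(1−R) − k2·R,   dG/dt = k3·R − k4·G,

with a GIRK current I = gmax·G⁴/(G⁴+kd)·(V−E_K) (outward for
V > −90 mV).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import AMPAParams, MGluR2Params

__all__ = [
    "AMPAState", "MGluR2State", "ampa_step", "mglur2_step",
    "ampa_equilibrium", "mglur2_equilibrium", "ampa_rate_matrix",
    "NormalizationError",
]

OCCUPANCY_TOL = 1e-6


class NormalizationError(RuntimeError):
    """AMPA occupancy drifted away from a total of 1."""


@dataclass
class AMPAState:
    """Occupancy of the four AMPA states (sums to 1)."""

    closed: float = 1.0
    open: float = 0.0
    desensitized: float = 0.0
    slow_open: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.closed, self.open, self.desensitized,
                         self.slow_open])

    @classmethod
    def from_array(cls, a) -> "AMPAState":
        return cls(float(a[0]), float(a[1]), float(a[2]), float(a[3]))

    @property
    def total(self) -> float:
        return self.closed + self.open + self.desensitized + self.slow_open


@dataclass
class MGluR2State:
    """Cascade state: bound-receptor fraction R ∈ [0,1] and G ≥ 0."""

    R: float = 0.0
    G: float = 0.0


def ampa_rate_matrix(p: AMPAParams, glu_mM: float) -> np.ndarray:
    """Generator matrix Q (column = source state, order C,O,D,S).

    Columns sum to zero; dx/dt = Q x.
    """
    a = p.kb * glu_mM ** p.hill_bind if glu_mM > 0 else 0.0
    Q = np.zeros((4, 4))
    Q[0, 0] = -a
    Q[1, 0] = a
    Q[0, 1] = p.ku
    Q[1, 1] = -(p.ku + p.kd)
    Q[2, 1] = p.kd
    Q[2, 2] = -p.krs
    Q[3, 2] = p.krs
    Q[3, 3] = -p.kc
    Q[0, 3] = p.kc
    return Q


def ampa_step(state: AMPAState, glu_mM: float, v_mV: float, dt: float,
              p: AMPAParams) -> tuple[AMPAState, float]:
    """One backward-Euler step; returns (new state, current in pA).

    The current is evaluated at the pre-step occupancy, matching the
    engine's record-then-update convention.  Outward positive.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if glu_mM < 0:
        raise ValueError("glutamate concentration must be >= 0")
    if abs(state.total - 1.0) > OCCUPANCY_TOL:
        raise NormalizationError(
            f"AMPA occupancy sum {state.total} drifted beyond {OCCUPANCY_TOL}")
    current = p.gmax_nS * (state.open + state.slow_open) * (v_mV - p.erev)
    a = p.kb * glu_mM ** p.hill_bind if glu_mM > 0 else 0.0
    al = 1.0 + dt * (p.ku + p.kd)
    be = 1.0 + dt * p.krs
    ga = 1.0 + dt * p.kc
    pO = state.open / al
    qO = dt * a / al
    pD = (state.desensitized + dt * p.kd * pO) / be
    qD = dt * p.kd * qO / be
    pS = (state.slow_open + dt * p.krs * pD) / ga
    qS = dt * p.krs * qD / ga
    c_new = (state.closed + dt * p.ku * pO + dt * p.kc * pS) / (
        1.0 + dt * a - dt * p.ku * qO - dt * p.kc * qS)
    new = AMPAState(c_new, pO + qO * c_new, pD + qD * c_new, pS + qS * c_new)
    return new, float(current)


def mglur2_step(state: MGluR2State, glu_mM: float, v_mV: float, dt: float,
                p: MGluR2Params) -> tuple[MGluR2State, float]:
    """One exact-exponential step; returns (new state, current in pA)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if glu_mM < 0:
        raise ValueError("glutamate concentration must be >= 0")
    gp = state.G ** p.hill_n
    current = p.gmax_nS * gp / (gp + p.kd) * (v_mV - p.erev)
    a = p.k1 * glu_mM ** p.hill_bind if glu_mM > 0 else 0.0
    tot = a + p.k2
    if tot > 0:
        rinf = a / tot
        r_new = rinf + (state.R - rinf) * np.exp(-dt * tot)
    else:
        r_new = state.R
    if p.k4 > 0:
        ginf = p.k3 * r_new / p.k4
        g_new = ginf + (state.G - ginf) * np.exp(-dt * p.k4)
    else:
        g_new = state.G + dt * p.k3 * r_new
    return MGluR2State(float(r_new), float(g_new)), float(current)


def ampa_equilibrium(p: AMPAParams, glu_mM: float) -> np.ndarray:
    """Stationary occupancy at constant glutamate (null space of Q)."""
    Q = ampa_rate_matrix(p, glu_mM)
    A = np.vstack([Q, np.ones(4)])
    b = np.zeros(5)
    b[-1] = 1.0
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    return x


def mglur2_equilibrium(p: MGluR2Params, glu_mM: float) -> MGluR2State:
    """Fixed point of the cascade at constant glutamate."""
    a = p.k1 * glu_mM ** p.hill_bind if glu_mM > 0 else 0.0
    r = a / (a + p.k2) if (a + p.k2) > 0 else 0.0
    g = p.k3 * r / p.k4 if p.k4 > 0 else float("inf")
    return MGluR2State(float(r), float(g))
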