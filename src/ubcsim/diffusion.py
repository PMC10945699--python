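"""Glutamate volume-transmission transients from point-source release.

A release of N molecules at distance r spreads through tortuous
extracellular space following the 3D porous-medium diffusion kernel

    C(r, t) = N / (α · (4π D* t)^{3/2}) · exp(−r² / (4 D* t)),

with D* = D/λ² the effective diffusion coefficient and α the
extracellular volume fraction (Nicholson convention).  Concentrations
are returned in mM (1 molecule/µm³ = 1.66054e-9 M).
"""

from __future__ import annotations

import numpy as np

from .params import DiffusionParams, MOLECULES_PER_UM3_TO_MM

__all__ = [
    "point_source_concentration",
    "peak_time",
    "peak_concentration",
    "transient_template",
    "concentration_waveform",
    "mglur2_params_from_ampa",
    "SingularityError",
]


class SingularityError(ValueError):
    """Concentration requested exactly at the source at t = 0."""


def point_source_concentration(t_since_release, p: DiffusionParams):
    """Concentration (mM) at distance ``p.distance_r`` a time
    ``t_since_release`` (ms) after one release event.

    Accepts scalars or arrays.  C(0) is defined as 0 off the source;
    at the source (r = 0) the kernel is singular at t = 0.
    """
    t = np.asarray(t_since_release, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_release must be >= 0")
    if p.distance_r == 0 and np.any(t == 0):
        raise SingularityError("point-source kernel is singular at r=0, t=0")
    d_eff = p.d_eff
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = p.n_molecules * MOLECULES_PER_UM3_TO_MM / (
            p.volume_fraction_alpha * (4.0 * np.pi * d_eff * t) ** 1.5
        )
        c = pref * np.exp(-p.distance_r**2 / (4.0 * d_eff * t))
    c = np.where(t > 0, c, 0.0)
    if np.ndim(t_since_release) == 0:
        return float(c)
    return c


def peak_time(p: DiffusionParams) -> float:
    """Analytic time-to-peak r²λ²/(6D) = r²/(6D*) in ms."""
    return p.distance_r**2 / (6.0 * p.d_eff)


def peak_concentration(p: DiffusionParams) -> float:
    """Concentration at the analytic peak time (mM)."""
    return point_source_concentration(peak_time(p), p)


def transient_template(p: DiffusionParams, dt: float, n: int) -> np.ndarray:
    """Single-event transient sampled on a uniform grid of ``n`` points.

    Element i holds C(i·dt); element 0 is 0 (off-source limit).
    """
    t = np.arange(n) * dt
    return point_source_concentration(t, p)


def concentration_waveform(event_times, p: DiffusionParams, t_grid,
                           template: np.ndarray | None = None) -> np.ndarray:
    """Superpose per-event transients plus ambient on ``t_grid`` (ms).

    ``t_grid`` must be uniform.  Events are snapped to the nearest grid
    point (error ≤ dt/2); duplicates sum.  An optional precomputed
    ``template`` (from :func:`transient_template` on the same grid
    spacing) avoids recomputing the kernel per event.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    n = t_grid.size
    if n < 2:
        raise ValueError("t_grid must have at least 2 points")
    dt = t_grid[1] - t_grid[0]
    steps = np.diff(t_grid)
    if not np.allclose(steps, dt, rtol=1e-9, atol=1e-12):
        raise ValueError("t_grid must be uniform")
    if template is None:
        template = transient_template(p, dt, n)
    out = np.full(n, p.ambient_mM, dtype=float)
    t0 = t_grid[0]
    for te in np.sort(np.asarray(event_times, dtype=float)):
        k = int(round((te - t0) / dt))
        if k >= n:
            continue
        if k < 0:
            # event before the grid: add the tail that overlaps the grid
            shift = -k
            if shift < n:
                tail = point_source_concentration(
                    (np.arange(n) + shift) * dt, p)
                out += tail
            continue
        out[k:] += template[: n - k]
    return out


def mglur2_params_from_ampa(p_ampa: DiffusionParams) -> DiffusionParams:
    """Derive the mGluR2 diffusion parameters from the AMPA ones.

    mGluR2 receptors are farther from the release site: 10× fewer
    molecules, +1 µm distance, no ambient glutamate; everything else
    is copied.
    """
    return DiffusionParams(
        n_molecules=p_ampa.n_molecules / 10.0,
        distance_r=p_ampa.distance_r + 1.0,
        diff_coeff_D=p_ampa.diff_coeff_D,
        tortuosity_lambda=p_ampa.tortuosity_lambda,
        volume_fraction_alpha=p_ampa.volume_fraction_alpha,
        ambient_mM=0.0,
    )
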