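"""Parameter containers for UBC cell, synapse and diffusion models.

All densities are in S/cm² and µF/cm², potentials in mV, time in ms,
lengths in µm, point currents in pA.  The two cell parameterizations
(`on_cell_params`, `off_cell_params`) carry the reference conductance
densities and reversal potentials of the ON and OFF unipolar brush cell
models; the gating-scheme rate constants are this package's own
calibrated values (see docs/methods.md) and are fully config-exposed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping

import yaml

__all__ = [
    "ConductanceSpec",
    "CellParams",
    "DiffusionParams",
    "AMPAParams",
    "MGluR2Params",
    "on_cell_params",
    "off_cell_params",
    "ampa_diffusion_params",
    "mglur2_diffusion_params",
    "ampa_receptor_params",
    "mglur2_receptor_params",
    "cell_params_to_dict",
    "cell_params_from_dict",
    "save_config",
    "load_config",
]

CHANNEL_NAMES = ("Na", "K", "K_slow", "H", "pas")

#: mapping between internal channel names and the config/table row names
CONFIG_KEYS = {
    "Na": "gNa",
    "K": "gK",
    "K_slow": "gKslow",
    "H": "gH",
    "pas": "gpas",
}
_CONFIG_KEYS_INV = {v: k for k, v in CONFIG_KEYS.items()}

#: gating schemes understood by the integration engine
KINETICS_IDS = ("na_m3h", "k_n4", "kslow_s", "h_q", "identity")


class InvalidParameterError(ValueError):
    """Raised for physically meaningless model parameters."""


@dataclass(frozen=True)
class ConductanceSpec:
    """One membrane conductance: density, reversal and gating scheme.

    ``kinetic_params`` holds the rate/shape constants of the gating
    scheme named by ``kinetics_id``; the passive leak uses the identity
    gate (open probability ≡ 1) and takes no kinetic parameters.
    """

    name: str
    gmax: float  # S/cm²
    erev: float  # mV
    kinetics_id: str
    kinetic_params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in CHANNEL_NAMES:
            raise InvalidParameterError(f"unknown channel name {self.name!r}")
        if not self.gmax >= 0:
            raise InvalidParameterError(f"gmax must be >= 0, got {self.gmax}")
        if not (-120.0 <= self.erev <= 60.0):
            raise InvalidParameterError(
                f"erev {self.erev} mV outside [-120, 60] mV"
            )
        if self.kinetics_id not in KINETICS_IDS:
            raise InvalidParameterError(
                f"unknown kinetics_id {self.kinetics_id!r}"
            )
        if self.name == "pas" and self.kinetics_id != "identity":
            raise InvalidParameterError("leak conductance must use identity gate")
        object.__setattr__(self, "kinetic_params", dict(self.kinetic_params))


@dataclass(frozen=True)
class CellParams:
    """Full parameterization of a single-compartment UBC model."""

    subtype: str  # "ON" or "OFF"
    diameter: float  # µm
    conductances: tuple[ConductanceSpec, ...]
    v_init: float  # mV
    specific_capacitance: float = 1.0  # µF/cm²
    bias_pA: float = 0.0  # constant depolarizing bias, 0 unless calibrated

    def __post_init__(self):
        if self.subtype not in ("ON", "OFF"):
            raise InvalidParameterError(f"subtype must be ON/OFF, got {self.subtype!r}")
        if not self.diameter > 0:
            raise InvalidParameterError(f"diameter must be > 0, got {self.diameter}")
        if self.specific_capacitance < 0:
            raise InvalidParameterError("specific_capacitance must be >= 0")
        names = [c.name for c in self.conductances]
        if len(names) != len(set(names)):
            raise InvalidParameterError(f"duplicate conductance names: {names}")
        object.__setattr__(self, "conductances", tuple(self.conductances))

    def conductance(self, name: str) -> ConductanceSpec:
        for c in self.conductances:
            if c.name == name:
                return c
        raise KeyError(name)

    def with_gmax(self, **gmax_by_name: float) -> "CellParams":
        """Return a copy with the given channel densities replaced."""
        new = []
        for c in self.conductances:
            if c.name in gmax_by_name:
                new.append(replace(c, gmax=gmax_by_name.pop(c.name)))
            else:
                new.append(c)
        if gmax_by_name:
            raise KeyError(f"unknown channels: {sorted(gmax_by_name)}")
        return replace(self, conductances=tuple(new))


# ---------------------------------------------------------------------------
# gating-scheme kinetic constants (calibrated; see docs/methods.md)
# ---------------------------------------------------------------------------

# Gating time constants follow tau(V) = t0 + ta·exp(-((V - tv)/tw)²);
# steady states are Boltzmann sigmoids (negative slope k = gate activated
# by hyperpolarization).  The calibrated values differ between subtypes:
# the ON cell's sodium activation sits slightly more negative (lower
# rheobase, so the slow rebound EPSC re-ignites firing), and the OFF
# cell's sits low enough that its sodium window current destabilizes
# rest and the cell paces spontaneously.

# Transient Na: m³h.
ON_NA_KINETICS = dict(
    m_vhalf=-39.3369, m_k=6.0, m_t0=0.04, m_ta=0.10, m_tv=-35.0, m_tw=30.0,
    h_vhalf=-50.0, h_k=-7.0, h_t0=0.8, h_ta=6.0, h_tv=-52.0, h_tw=18.0,
)
OFF_NA_KINETICS = dict(ON_NA_KINETICS, m_vhalf=-41.5)

# Delayed-rectifier K: n⁴.  The slow subthreshold decay (n_ta at −60 mV)
# deepens the interspike AHP and caps burst firing near 30 Hz.
K_KINETICS = dict(
    n_vhalf=-36.0, n_k=8.0, n_t0=1.5, n_ta=33.0, n_tv=-60.0, n_tw=18.0,
)

# Slow non-inactivating K (spike-frequency adaptation): single gate s.
KSLOW_KINETICS = dict(
    s_vhalf=-45.0, s_k=4.0, s_t0=30.0, s_ta=0.0, s_tv=0.0, s_tw=1.0,
)

# Hyperpolarization-activated cation conductance (Ih): single gate q,
# activated by hyperpolarization (negative slope).  The OFF cell's
# half-activation is far below rest, so with its 30× larger gH density
# the standing Ih stays comparable to the ON cell's and the sag appears
# only on strong hyperpolarization.
ON_H_KINETICS = dict(
    q_vhalf=-78.0, q_k=-9.0, q_t0=250.0, q_ta=0.0, q_tv=0.0, q_tw=1.0,
)
OFF_H_KINETICS = dict(ON_H_KINETICS, q_vhalf=-116.0)

#: kept for backwards-compatible config round-trips
NA_KINETICS = ON_NA_KINETICS
H_KINETICS = ON_H_KINETICS


def _make_cell(subtype, diameter, gna, gk, gh, gpas, gkslow, e_pas, v_init,
               na_kin, h_kin, bias_pA=0.0):
    cond = (
        ConductanceSpec("Na", gna, 50.0, "na_m3h", na_kin),
        ConductanceSpec("K", gk, -90.0, "k_n4", K_KINETICS),
        ConductanceSpec("K_slow", gkslow, -90.0, "kslow_s", KSLOW_KINETICS),
        ConductanceSpec("H", gh, -30.0, "h_q", h_kin),
        ConductanceSpec("pas", gpas, e_pas, "identity"),
    )
    return CellParams(subtype=subtype, diameter=diameter, conductances=cond,
                      v_init=v_init, bias_pA=bias_pA)


def on_cell_params() -> CellParams:
    """ON UBC model: quiescent at rest, driven by the AMPA synapse.

    Conductance densities and reversals follow the reference ON UBC
    table (gNa 0.1 S/cm² @ +50 mV, gK 0.03 @ −90, gH 1e-5 @ −30,
    gpas 2e-4 @ −65, gKslow 8e-4 @ −90, diameter 20 µm).
    """
    return _make_cell("ON", 20.0, 0.1, 0.03, 1e-5, 2e-4, 8e-4, -65.0, -70.0,
                      ON_NA_KINETICS, ON_H_KINETICS)


def off_cell_params() -> CellParams:
    """OFF UBC model: spontaneously active, inhibited via mGluR2.

    Densities follow the reference OFF UBC table (gH 3.1e-4 @ −30,
    gpas 7e-5 @ −62, diameter 27 µm); the depolarized leak reversal and
    the sodium window current make the cell an intrinsic pacemaker
    (~9 Hz, clock-like).
    """
    return _make_cell("OFF", 27.0, 0.1, 0.03, 3.1e-4, 7e-5, 8e-4, -62.0,
                      -60.0, OFF_NA_KINETICS, OFF_H_KINETICS)


# ---------------------------------------------------------------------------
# glutamate diffusion
# ---------------------------------------------------------------------------

#: 1 molecule/µm³ in mM (1.66054e-9 M)
MOLECULES_PER_UM3_TO_MM = 1.66054e-6


@dataclass(frozen=True)
class DiffusionParams:
    """Point-source diffusion of glutamate through neuropil.

    The free diffusion coefficient ``diff_coeff_D`` is in µm²/ms
    (0.33 µm²/ms = 3.3e-6 cm²/s, the standard value for glutamate);
    tortuosity slows it to D* = D/λ² and the extracellular volume
    fraction α concentrates the released molecules.
    """

    n_molecules: float = 3e6
    distance_r: float = 0.75  # µm
    diff_coeff_D: float = 0.33  # µm²/ms
    tortuosity_lambda: float = 1.55
    volume_fraction_alpha: float = 0.21
    ambient_mM: float = 0.005

    def __post_init__(self):
        if self.n_molecules < 0 or self.distance_r < 0 or self.diff_coeff_D < 0:
            raise InvalidParameterError("diffusion parameters must be >= 0")
        if self.tortuosity_lambda < 1:
            raise InvalidParameterError("tortuosity must be >= 1")
        if not (0 < self.volume_fraction_alpha <= 1):
            raise InvalidParameterError("volume fraction must be in (0, 1]")
        if self.ambient_mM < 0:
            raise InvalidParameterError("ambient glutamate must be >= 0")

    @property
    def d_eff(self) -> float:
        """Effective diffusion coefficient D* = D/λ² (µm²/ms)."""
        return self.diff_coeff_D / self.tortuosity_lambda**2


def ampa_diffusion_params() -> DiffusionParams:
    """Diffusion parameters at the AMPA receptor (ON UBC synapse)."""
    return DiffusionParams()


def mglur2_diffusion_params() -> DiffusionParams:
    """Diffusion parameters at the mGluR2 receptor (OFF UBC synapse).

    mGluR2 receptors sit farther from release sites: 10× fewer molecules
    reach them and the distance is 1 µm greater, with no ambient term.
    """
    return DiffusionParams(n_molecules=3e5, distance_r=1.75, ambient_mM=0.0)


# ---------------------------------------------------------------------------
# receptor schemes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AMPAParams:
    """Cyclic AMPA receptor scheme C ⇄ O → D → S → C.

    O is the fast open state (classic EPSC); D a desensitized state;
    S a slowly closing open conformation entered on recovery from
    desensitization, which carries the slow rebound EPSC that drives
    the ON UBC's prolonged burst.  Rates are calibrated against the
    single-cell burst anchors; ``gmax_S`` and ``erev`` are fixed by the
    reference synaptic-conductance table.
    """

    kb: float = 0.108601  # C→O binding+opening, mM⁻ⁿms⁻¹ (glutamate-dep.)
    ku: float = 0.25  # O→C closing, ms⁻¹
    kd: float = 0.0215630  # O→D desensitization, ms⁻¹
    krs: float = 0.0570167  # D→S recovery into slow-open, ms⁻¹
    kc: float = 0.00257926  # S→C slow closing, ms⁻¹ (sets rebound decay τ)
    hill_bind: float = 2.0  # binding cooperativity (two glutamates to open)
    gmax_S: float = 4e-9  # total synaptic conductance, S
    erev: float = 0.0  # mV

    def __post_init__(self):
        for f in ("kb", "ku", "kd", "krs", "kc", "gmax_S"):
            if getattr(self, f) < 0:
                raise InvalidParameterError(f"{f} must be >= 0")

    @property
    def gmax_nS(self) -> float:
        return self.gmax_S * 1e9


@dataclass(frozen=True)
class MGluR2Params:
    """mGluR2 → G protein → GIRK cascade (modified GABA-B scheme).

    dR/dt = k1·T·(1−R) − k2·R, dG/dt = k3·R − k4·G and the potassium
    current gates as G⁴/(G⁴ + kd).  The unbinding rate k2 is fixed at
    0.0215 ms⁻¹; the cascade rates are calibration outputs.
    """

    k1: float = 54.1631  # binding, mM⁻ⁿms⁻¹
    k2: float = 0.0215  # unbinding, ms⁻¹
    k3: float = 0.41  # G production, ms⁻¹
    k4: float = 0.00305965  # G decay, ms⁻¹
    kd: float = 100.0  # half-activation, units of G^n
    hill_n: float = 4.0
    hill_bind: float = 2.0  # effective binding cooperativity (dimeric receptor)
    gmax_S: float = 1e-8  # total GIRK conductance, S
    erev: float = -90.0  # mV

    def __post_init__(self):
        for f in ("k1", "k2", "k3", "k4", "kd", "hill_n", "gmax_S"):
            if getattr(self, f) < 0:
                raise InvalidParameterError(f"{f} must be >= 0")

    @property
    def gmax_nS(self) -> float:
        return self.gmax_S * 1e9


def ampa_receptor_params() -> AMPAParams:
    """Calibrated AMPA receptor parameters (ON UBC synapse)."""
    return AMPAParams()


def mglur2_receptor_params() -> MGluR2Params:
    """Calibrated mGluR2 cascade parameters (OFF UBC synapse)."""
    return MGluR2Params()


# ---------------------------------------------------------------------------
# config serialization (YAML; channel keys mirror the table row names)
# ---------------------------------------------------------------------------


def cell_params_to_dict(p: CellParams) -> dict:
    d = {
        "subtype": p.subtype,
        "diameter": p.diameter,
        "specific_capacitance": p.specific_capacitance,
        "v_init": p.v_init,
        "bias_pA": p.bias_pA,
        "channels": {},
    }
    for c in p.conductances:
        d["channels"][CONFIG_KEYS[c.name]] = {
            "gmax": c.gmax,
            "erev": c.erev,
            "kinetics_id": c.kinetics_id,
            "kinetic_params": dict(c.kinetic_params),
        }
    return d


def cell_params_from_dict(d: Mapping) -> CellParams:
    cond = []
    for key, ch in d["channels"].items():
        name = _CONFIG_KEYS_INV.get(key, key)
        cond.append(ConductanceSpec(
            name=name, gmax=float(ch["gmax"]), erev=float(ch["erev"]),
            kinetics_id=ch["kinetics_id"],
            kinetic_params=ch.get("kinetic_params", {}),
        ))
    cond.sort(key=lambda c: CHANNEL_NAMES.index(c.name))
    return CellParams(
        subtype=d["subtype"], diameter=float(d["diameter"]),
        conductances=tuple(cond), v_init=float(d["v_init"]),
        specific_capacitance=float(d.get("specific_capacitance", 1.0)),
        bias_pA=float(d.get("bias_pA", 0.0)),
    )


def _dataclass_to_dict(obj) -> dict:
    return dataclasses.asdict(obj)


def save_config(path, *, on_cell=None, off_cell=None, ampa=None, mglur2=None,
                diffusion_ampa=None, diffusion_mglur2=None, extra=None):
    """Write a full model configuration to a YAML file."""
    cfg = {}
    if on_cell is not None:
        cfg["on_cell"] = cell_params_to_dict(on_cell)
    if off_cell is not None:
        cfg["off_cell"] = cell_params_to_dict(off_cell)
    if ampa is not None:
        cfg["ampa_receptor"] = _dataclass_to_dict(ampa)
    if mglur2 is not None:
        cfg["mglur2_receptor"] = _dataclass_to_dict(mglur2)
    if diffusion_ampa is not None:
        cfg["diffusion_ampa"] = _dataclass_to_dict(diffusion_ampa)
    if diffusion_mglur2 is not None:
        cfg["diffusion_mglur2"] = _dataclass_to_dict(diffusion_mglur2)
    if extra:
        cfg.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def load_config(path) -> dict:
    """Load a YAML model configuration into parameter objects."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    out = {}
    if "on_cell" in cfg:
        out["on_cell"] = cell_params_from_dict(cfg["on_cell"])
    if "off_cell" in cfg:
        out["off_cell"] = cell_params_from_dict(cfg["off_cell"])
    if "ampa_receptor" in cfg:
        out["ampa_receptor"] = AMPAParams(**cfg["ampa_receptor"])
    if "mglur2_receptor" in cfg:
        out["mglur2_receptor"] = MGluR2Params(**cfg["mglur2_receptor"])
    if "diffusion_ampa" in cfg:
        out["diffusion_ampa"] = DiffusionParams(**cfg["diffusion_ampa"])
    if "diffusion_mglur2" in cfg:
        out["diffusion_mglur2"] = DiffusionParams(**cfg["diffusion_mglur2"])
    for k, v in cfg.items():
        out.setdefault(k, v)
    return out
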