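"""Physical constants and default parameters of the ventricular cell model.

The cell model is the 22-state guinea-pig ventricular myocyte model of
Noble, Varghese, Kohl & Noble (1998), "basic" variant, at physiological
temperature (310 K), with the inward-rectifier current I_K1 and the fast
sodium current I_Na exposed through free maximal conductances G_K1 and
G_Na (both 0.5 uS by default) and I_Na driven by the pure sodium Nernst
potential.

Unit system (self-consistent throughout the package):

=============  =====
quantity       unit
=============  =====
voltage        mV
time           ms
current        nA
conductance    uS
capacitance    nF
concentration  mM
volume         uL
=============  =====

so that uS x mV = nA and nF x mV/ms = nA.  Rate constants taken from the
reference model (stated per second) are converted to per millisecond when
the parameter vector is built.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import yaml

# Gas constant in mJ/(mol K), Faraday in C/mol: RT/F is then in mV.
GAS_CONSTANT_R = 8314.472
FARADAY_F = 96485.3415
TEMPERATURE_K = 310.0

#: schema version of the constants bundle (bump on any change of defaults)
CONSTANTS_VERSION = 1

# cell geometry: cylinder of radius 12 um and length 74 um; volumes in uL
_CELL_RADIUS_MM = 0.012
_CELL_LENGTH_MM = 0.074
_V_CELL = math.pi * _CELL_RADIUS_MM**2 * _CELL_LENGTH_MM  # mm^3 == uL


@dataclass(frozen=True)
class CellParameters:
    """Complete constant bundle of the single-cell model.

    The two conductances under study (``G_K1``, ``G_Na``) default to the
    0.5 uS baseline; every other constant is at the reference model's
    published value.  All entries are exposed so tests can pin them.
    """

    # --- the conductances under study -----------------------------------
    G_K1: float = 0.5          # uS, maximal inward-rectifier conductance
    G_Na: float = 0.5          # uS, maximal fast-sodium conductance

    # --- thermodynamics / geometry --------------------------------------
    R: float = GAS_CONSTANT_R  # mJ/(mol K)
    T: float = TEMPERATURE_K   # K
    F: float = FARADAY_F       # C/mol
    C_m: float = 0.095         # nF  (9.5e-5 uF)
    V_cell: float = _V_CELL    # uL
    V_i_ratio: float = 0.49    # cytosol fraction of cell volume
    V_ds_ratio: float = 0.1    # diadic space volume as fraction of cytosol
    V_up_ratio: float = 0.01   # SR uptake store fraction of cell volume
    V_rel_ratio: float = 0.1   # SR release store fraction of cell volume

    # --- fixed extracellular milieu --------------------------------------
    K_o: float = 5.4           # mM (physiological Tyrode; rest ~ -85 mV)
    Na_o: float = 140.0        # mM
    Ca_o: float = 2.0          # mM

    # --- I_K1 -------------------------------------------------------------
    k_mK1: float = 10.0        # mM, external-K half-saturation of I_K1
    #: steepness factor of the inward rectification: the exponent is
    #: (V - E_K - 10) * K1_steepness * F/RT.  1.25 is the reference
    #: model's value (slope ~21.4 mV at 310 K); 2.0 gives an RT/2F slope
    #: (~13.4 mV) under which I_K1 vanishes at plateau potentials.
    K1_steepness: float = 1.25

    # --- I_Na family ------------------------------------------------------
    g_pNa: float = 0.004       # uS, persistent (late) sodium
    g_bNa: float = 0.0006      # uS, background sodium
    delta_m: float = 1e-5      # mV, singularity guard for alpha_m
    #: K+ permeability fraction of the fast/persistent sodium channel.
    #: The channel reversal is E_Na = RT/F ln((Na_o + P_mh K_o)/(Na_i + P_mh K_i));
    #: 0.12 is the reference model's mixed Na/K reversal (set 0 for the pure
    #: sodium Nernst potential).
    P_mh: float = 0.12

    # --- delayed rectifiers and transient outward -------------------------
    g_Kr1: float = 0.0021      # uS, fast component of i_Kr
    g_Kr2: float = 0.0013      # uS, slow component of i_Kr
    g_Ks: float = 0.0026       # uS
    P_kna: float = 0.03        # Na permeability fraction of E_Ks
    g_to: float = 0.005        # uS
    g_tos: float = 0.0         # fraction of s-gate-independent i_to

    # --- L-type calcium current ------------------------------------------
    P_Ca_L: float = 0.1        # nA/mM
    P_CaK: float = 0.002       # relative K permeability
    P_CaNa: float = 0.01       # relative Na permeability
    FrICa: float = 1.0         # fraction of i_CaL facing the diadic space
    speed_d: float = 3.0       # dimensionless rate multiplier of the d gate
    speed_f: float = 0.3       # dimensionless rate multiplier of the f gate
    Km_f2: float = 1.0e5       # mM (cytosolic Ca inactivation disabled)
    Km_f2ds: float = 0.001     # mM, diadic-space Ca inactivation
    R_decay: float = 20.0      # 1/s, f2ds recovery rate

    # --- background calcium ----------------------------------------------
    g_bCa: float = 0.00025     # uS

    # --- Na/K pump --------------------------------------------------------
    i_NaK_max: float = 0.7     # nA
    K_mK: float = 1.0          # mM
    K_mNa: float = 40.0        # mM

    # --- Na/Ca exchanger --------------------------------------------------
    k_NaCa: float = 0.0005     # nA scaling
    gamma_NaCa: float = 0.5
    n_NaCa: float = 3.0
    d_NaCa: float = 0.0
    FRiNaCa: float = 0.001     # fraction of exchanger facing diadic space

    # --- SR calcium handling ----------------------------------------------
    K_cyca: float = 0.0003     # mM
    K_xcs: float = 0.4
    K_srca: float = 0.5        # mM
    alpha_up: float = 0.4      # mM/s
    beta_up: float = 0.03      # mM/s
    K_m_rel: float = 250.0     # 1/s
    K_leak_rate: float = 0.05  # 1/s
    K_trans: float = 50.0      # 1/s, uptake-to-release translocation
    K_m_Ca_cyt: float = 0.0005  # mM, cytosolic Ca regulation of release
    K_m_Ca_ds: float = 0.01    # mM, diadic Ca regulation of release
    K_act_rate: float = 500.0  # 1/s, release activation coefficient
    K_inact_base: float = 60.0  # 1/s, release inactivation floor
    K_prod_decay: float = 1.0  # 1/s, decay of the inactivated fraction
    Kdecay: float = 10.0       # 1/s, diadic-space Ca decay into cytosol

    # --- cytosolic calcium buffers ----------------------------------------
    Calmod_total: float = 0.02    # mM
    Trop_total: float = 0.05      # mM
    alpha_Calmod: float = 1.0e5   # 1/(mM s)
    beta_Calmod: float = 50.0     # 1/s
    alpha_Trop: float = 1.0e5     # 1/(mM s)
    beta_Trop: float = 200.0      # 1/s

    def __post_init__(self) -> None:
        for name in ("G_K1", "G_Na", "C_m", "K_o", "k_mK1"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    # ------------------------------------------------------------------
    @property
    def RTF(self) -> float:
        """Thermal voltage RT/F in mV (~26.71 mV at 310 K)."""
        return self.R * self.T / self.F

    @property
    def V_i(self) -> float:
        """Cytosolic volume in uL."""
        return self.V_cell * self.V_i_ratio

    def replace(self, **kw) -> "CellParameters":
        d = asdict(self)
        d.update(kw)
        return CellParameters(**d)

    # ------------------------------------------------------------------
    def to_vector(self) -> np.ndarray:
        """Pack into the flat float64 vector consumed by the RHS kernel.

        Per-second rate constants are converted to per-millisecond here,
        keeping the kernel free of unit juggling.
        """
        ms = 1e-3  # per-second -> per-millisecond
        rtf = self.RTF
        v_i = self.V_i
        return np.array([
            self.C_m,                      # 0
            rtf,                           # 1
            self.K_o,                      # 2
            self.Na_o,                     # 3
            self.Ca_o,                     # 4
            self.G_K1,                     # 5
            self.k_mK1,                    # 6
            self.G_Na,                     # 7
            self.g_pNa,                    # 8
            self.g_bNa,                    # 9
            self.g_Kr1,                    # 10
            self.g_Kr2,                    # 11
            self.g_Ks,                     # 12
            self.P_kna,                    # 13
            self.g_to,                     # 14
            self.g_tos,                    # 15
            self.P_Ca_L,                   # 16
            self.P_CaK,                    # 17
            self.P_CaNa,                   # 18
            self.FrICa,                    # 19
            self.speed_d * ms,             # 20 (gate rates folded to /ms)
            self.speed_f * ms,             # 21
            self.Km_f2,                    # 22
            self.Km_f2ds,                  # 23
            self.R_decay * ms,             # 24
            self.g_bCa,                    # 25
            self.i_NaK_max,                # 26
            self.K_mK,                     # 27
            self.K_mNa,                    # 28
            self.k_NaCa,                   # 29
            self.gamma_NaCa,               # 30
            self.n_NaCa,                   # 31
            self.d_NaCa,                   # 32
            self.FRiNaCa,                  # 33
            self.K_cyca,                   # 34
            self.K_xcs,                    # 35
            self.K_srca,                   # 36
            self.alpha_up * ms,            # 37
            self.beta_up * ms,             # 38
            self.K_m_rel * ms,             # 39
            self.K_leak_rate * ms,         # 40
            self.K_trans * ms,             # 41
            self.K_m_Ca_cyt,               # 42
            self.K_m_Ca_ds,                # 43
            self.K_act_rate * ms,          # 44
            self.K_inact_base * ms,        # 45
            self.K_prod_decay * ms,        # 46
            self.Kdecay * ms,              # 47
            self.Calmod_total,             # 48
            self.Trop_total,               # 49
            self.alpha_Calmod * ms,        # 50
            self.beta_Calmod * ms,         # 51
            self.alpha_Trop * ms,          # 52
            self.beta_Trop * ms,           # 53
            1.0 / (self.F * v_i) * ms,     # 54  nA -> mM/ms (monovalent)
            self.V_i_ratio,                # 55
            self.V_up_ratio,               # 56
            self.V_rel_ratio,              # 57
            self.V_ds_ratio,               # 58
            self.delta_m,                  # 59
            self.P_mh,                     # 60
            self.K1_steepness,             # 61
        ], dtype=np.float64)


#: ordered names of the 22 state variables (cell-major flattening contract)
STATE_NAMES = (
    "V",        # membrane potential, mV
    "m",        # i_Na activation
    "h",        # i_Na inactivation
    "d",        # i_CaL activation
    "f",        # i_CaL voltage inactivation
    "f2",       # i_CaL cytosolic Ca inactivation
    "f2ds",     # i_CaL diadic-space Ca inactivation
    "xr1",      # i_Kr fast activation
    "xr2",      # i_Kr slow activation
    "xs",       # i_Ks activation
    "s",        # i_to inactivation
    "r",        # i_to activation
    "ActFrac",  # SR release channel activated fraction
    "ProdFrac",  # SR release channel inactivated fraction
    "Na_i",     # mM
    "K_i",      # mM
    "Ca_i",     # mM
    "Ca_ds",    # mM
    "Ca_up",    # mM
    "Ca_rel",   # mM
    "Ca_Calmod",  # mM, Ca bound to calmodulin
    "Ca_Trop",  # mM, Ca bound to troponin
)

N_STATES = len(STATE_NAMES)  # 22

#: reference initial state (quiescent-ish; resting_state() refines it)
INITIAL_STATE = np.array([
    -92.849333,    # V
    0.0016203,     # m
    0.9944036,     # h
    0.0,           # d
    1.0,           # f
    0.9349197,     # f2
    0.9651958,     # f2ds
    1.03e-5,       # xr1
    2.0e-7,        # xr2
    0.001302,      # xs
    0.9948645,     # s
    0.0,           # r
    0.0042614,     # ActFrac
    0.4068154,     # ProdFrac
    7.3321223,     # Na_i
    136.5644281,   # K_i
    1.4e-5,        # Ca_i
    1.88e-5,       # Ca_ds
    0.4531889,     # Ca_up
    0.4481927,     # Ca_rel
    0.0005555,     # Ca_Calmod
    0.0003542,     # Ca_Trop
], dtype=np.float64)

GATE_INDICES = tuple(range(1, 14))       # gates & SR fractions live in [0, 1]
CONCENTRATION_INDICES = tuple(range(14, 22))


def dump_constants(path: str | Path, params: CellParameters | None = None) -> None:
    """Write the constants bundle to a versioned YAML file."""
    params = params or CellParameters()
    doc = {"version": CONSTANTS_VERSION, "units": "mV ms nA uS nF mM uL",
           "parameters": asdict(params)}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_constants(path: str | Path) -> CellParameters:
    """Read a constants bundle written by :func:`dump_constants`."""
    doc = yaml.safe_load(Path(path).read_text())
    return CellParameters(**doc["parameters"])


def parameter_names() -> list[str]:
    return [f.name for f in fields(CellParameters)]
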