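"""Single-cell ionic model: currents, derivatives, resting state.

The membrane model is the 22-state guinea-pig ventricular myocyte of
Noble, Varghese, Kohl & Noble (1998) with the inward rectifier I_K1 and
fast sodium current I_Na exposed explicitly:

    I_K1 = G_K1 * [K]_o/([K]_o + k_mK1) * (V - E_K)
           / (1 + exp((V - E_K - 10) * s * F/(RT)))

    I_Na = G_Na * m^3 * h * (V - E_Na)

with E_K the potassium Nernst potential, s the rectification steepness
(1.25 in the reference model, giving a ~21 mV slope at 310 K), and E_Na
the sodium-channel reversal (mixed Na/K, see :func:`sodium_reversal`).
Outward currents are positive; a negative current is inward.
Units: mV, ms, nA, uS, nF, mM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import _kernel
from .constants import (CellParameters, CONCENTRATION_INDICES, GATE_INDICES,
                        INITIAL_STATE, N_STATES, STATE_NAMES)

__all__ = [
    "CellParameters", "CellState", "CurrentSet",
    "compute_IK1", "compute_INa", "nernst_potassium", "nernst_sodium",
    "sodium_reversal",
    "cell_derivatives", "currents", "resting_state", "validate_state",
]

CURRENT_NAMES = (
    "i_K1", "i_Na", "i_p_Na", "i_b_Na", "i_Kr", "i_Ks", "i_to",
    "i_CaL_Ca_cyt", "i_CaL_Ca_ds", "i_CaL_K_cyt", "i_CaL_K_ds",
    "i_CaL_Na_cyt", "i_CaL_Na_ds", "i_b_Ca", "i_NaK",
    "i_NaCa_cyt", "i_NaCa_ds",
)


class CellState:
    """Named view over the 22-component state vector of one cell.

    The underlying array (``.vector``) is the contract used throughout the
    package; this wrapper adds validation, attribute access and JSON
    round-tripping for fixtures.
    """

    __slots__ = ("vector",)

    def __init__(self, vector):
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (N_STATES,):
            raise ValueError(
                f"state vector must have length {N_STATES}, got {vector.shape}")
        object.__setattr__(self, "vector", vector)

    def __getattr__(self, name):
        try:
            return self.vector[STATE_NAMES.index(name)]
        except ValueError:
            raise AttributeError(name) from None

    def __setattr__(self, name, value):
        if name in STATE_NAMES:
            self.vector[STATE_NAMES.index(name)] = value
        else:
            raise AttributeError(name)

    def copy(self) -> "CellState":
        return CellState(self.vector.copy())

    def to_dict(self) -> dict:
        return dict(zip(STATE_NAMES, map(float, self.vector)))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CellState":
        d = json.loads(Path(path).read_text())
        return cls([d[k] for k in STATE_NAMES])

    @classmethod
    def reference(cls) -> "CellState":
        return cls(INITIAL_STATE.copy())


def validate_state(vector: np.ndarray, *, strict: bool = True) -> None:
    """Check gate bounds and concentration positivity of a state vector."""
    v = np.asarray(vector, dtype=float)
    if v.shape[-1] != N_STATES:
        raise ValueError(f"state vector length must be {N_STATES}")
    gates = v[..., list(GATE_INDICES)]
    conc = v[..., list(CONCENTRATION_INDICES)]
    ok = (np.all(gates >= -1e-9) and np.all(gates <= 1.0 + 1e-9)
          and np.all(conc > 0) and np.all(np.isfinite(v)))
    if strict and not ok:
        raise ValueError("invalid cell state: gate out of [0,1], "
                         "non-positive concentration, or non-finite entry")
    return ok


@dataclass(frozen=True)
class CurrentSet:
    """Instantaneous membrane currents of one cell (nA, outward positive)."""

    I_K1: float
    I_Na: float
    I_ion_total: float
    components: dict

    def __post_init__(self):
        s = sum(self.components.values())
        if abs(s - self.I_ion_total) > 1e-12 * max(1.0, abs(s)):
            raise ValueError("I_ion_total does not equal the component sum")


def nernst_potassium(params: CellParameters, K_i: float) -> float:
    """Potassium Nernst potential E_K in mV."""
    return params.RTF * np.log(params.K_o / K_i)


def nernst_sodium(params: CellParameters, Na_i: float) -> float:
    """Sodium Nernst potential E_Na in mV."""
    return params.RTF * np.log(params.Na_o / Na_i)


def compute_IK1(V_m, params: CellParameters, K_i: float | None = None):
    """Inward-rectifier potassium current (nA) at membrane potential ``V_m``.

    ``K_i`` defaults to the reference resting internal potassium; pass the
    instantaneous value when evaluating along a trajectory.
    """
    V_m = np.asarray(V_m, dtype=float)
    if not np.all(np.isfinite(V_m)):
        raise ValueError("V_m must be finite")
    if K_i is None:
        K_i = float(INITIAL_STATE[STATE_NAMES.index("K_i")])
    E_K = nernst_potassium(params, K_i)
    sat = params.K_o / (params.K_o + params.k_mK1)
    rect = 1.0 + np.exp((V_m - E_K - 10.0) * params.K1_steepness / params.RTF)
    out = params.G_K1 * sat * (V_m - E_K) / rect
    return out if out.ndim else float(out)


def sodium_reversal(params: CellParameters, Na_i: float,
                    K_i: float) -> float:
    """Reversal potential of the fast sodium channel (mV).

    The channel carries a small potassium leak (fraction ``P_mh``), so
    E_Na = RT/F ln((Na_o + P_mh K_o)/(Na_i + P_mh K_i)); with P_mh = 0
    this is the pure sodium Nernst potential.
    """
    return params.RTF * np.log((params.Na_o + params.P_mh * params.K_o)
                               / (Na_i + params.P_mh * K_i))


def compute_INa(V_m, m, h, params: CellParameters,
                Na_i: float | None = None, K_i: float | None = None):
    """Fast sodium current G_Na m^3 h (V - E_Na) in nA."""
    m = np.asarray(m, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any((m < 0) | (m > 1) | (h < 0) | (h > 1)):
        raise ValueError("gates m, h must lie in [0, 1]")
    if Na_i is None:
        Na_i = float(INITIAL_STATE[STATE_NAMES.index("Na_i")])
    if K_i is None:
        K_i = float(INITIAL_STATE[STATE_NAMES.index("K_i")])
    E_Na = sodium_reversal(params, Na_i, K_i)
    out = params.G_Na * m**3 * h * (np.asarray(V_m, dtype=float) - E_Na)
    return out if out.ndim else float(out)


def currents(state, params: CellParameters) -> CurrentSet:
    """All membrane currents of one cell at ``state``."""
    y = state.vector if isinstance(state, CellState) else np.asarray(state, float)
    if y.shape != (N_STATES,):
        raise ValueError(f"state vector length must be {N_STATES}")
    cur = np.empty(_kernel.N_CURRENTS)
    total = _kernel._cell_currents(y, params.to_vector(), cur)
    comp = dict(zip(CURRENT_NAMES, map(float, cur)))
    return CurrentSet(I_K1=comp["i_K1"], I_Na=comp["i_Na"],
                      I_ion_total=float(total), components=comp)


def cell_derivatives(state, t: float, params: CellParameters,
                     I_ext: float = 0.0) -> np.ndarray:
    """Full 22-component time derivative of one cell (units per ms).

    ``I_ext`` is the total external current into the cell (stimulus and/or
    coupling), inward-negative, entering as C_m dV/dt = -(I_ion + I_ext).
    The model is autonomous; ``t`` is accepted for ODE-solver signatures.
    """
    y = state.vector if isinstance(state, CellState) else np.asarray(state, float)
    if y.shape != (N_STATES,):
        raise ValueError(f"state vector length must be {N_STATES}")
    dy = np.empty(N_STATES)
    cur = np.empty(_kernel.N_CURRENTS)
    _kernel._cell_rhs(y, float(I_ext), params.to_vector(), dy, cur)
    return dy


def resting_state(params: CellParameters | None = None, *,
                  t_settle: float = 20_000.0, tol: float = 1e-6,
                  y0: np.ndarray | None = None) -> CellState:
    """Quiescent steady state of the unstimulated cell.

    Integrates from the reference initial conditions for ``t_settle`` ms
    and then polishes the end point by root-finding on the full RHS.
    Raises if no rest point with finite, valid states is found — this
    happens in oscillatory or pathological parameter regimes.

    The returned state satisfies max-norm(RHS) < ``tol`` in model units.
    """
    params = params or CellParameters()
    P = params.to_vector()
    cur = np.empty(_kernel.N_CURRENTS)
    dy = np.empty(N_STATES)

    def rhs(t, y):
        _kernel._cell_rhs(y, 0.0, P, dy, cur)
        return dy.copy()

    y0 = INITIAL_STATE.copy() if y0 is None else np.asarray(y0, float).copy()
    y_rest = None
    for settle in (t_settle, 10 * t_settle):
        sol = solve_ivp(rhs, (0.0, settle), y0, method="LSODA",
                        rtol=1e-8, atol=1e-8, dense_output=False)
        if not sol.success:
            raise RuntimeError(
                f"settling integration failed for parameters {params.G_K1=}, "
                f"{params.G_Na=}: {sol.message}")
        guess = sol.y[:, -1]
        # root-find in scaled variables (states span ~1e-7 .. 1e2);
        # success is judged on the residual norm, not the solver flag
        scale = np.maximum(np.abs(guess), 1e-6)
        res = root(lambda z: rhs(0.0, z * scale), guess / scale,
                   method="hybr", options={"xtol": 1e-14, "maxfev": 20000})
        cand = res.x * scale
        if (np.max(np.abs(rhs(0.0, cand))) < tol
                and validate_state(cand, strict=False)):
            y_rest = cand
            break
    if y_rest is None:
        raise RuntimeError(
            "no quiescent rest point found (oscillatory or pathological "
            f"regime?) for G_K1={params.G_K1} uS, G_Na={params.G_Na} uS")
    return CellState(y_rest)
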