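"""Numerical right-hand-side kernel of the 22-state ventricular cell model.

Everything here operates on flat float64 arrays so the same compiled code
serves a single cell and a fiber of N cells (cell-major flattening: all 22
states of cell 1, then cell 2, ...).  The functions are JIT-compiled with
numba when available; the pure-Python fallbacks are identical code.

Gate rate constants are written in the reference model's per-second form
and converted with ``MS`` = 1e-3; every parameter the kernel reads comes
pre-scaled from :meth:`cardiofiber.constants.CellParameters.to_vector`.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f
        return wrap

MS = 1e-3  # per-second -> per-millisecond

N_STATES = 22

# current vector layout (see currents() in cell_model for the named map)
N_CURRENTS = 17
(I_K1, I_NA, I_PNA, I_BNA, I_KR, I_KS, I_TO,
 I_CAL_CA_CYT, I_CAL_CA_DS, I_CAL_K_CYT, I_CAL_K_DS,
 I_CAL_NA_CYT, I_CAL_NA_DS, I_BCA, I_NAK,
 I_NACA_CYT, I_NACA_DS) = range(N_CURRENTS)


@njit(cache=False)
def _exp(x):
    """exp with an overflow guard; solvers probe extreme trial states."""
    if x > 700.0:
        x = 700.0
    return math.exp(x)


@njit(cache=False)
def m_gate_rates(V, delta_m):
    """alpha, beta of the sodium activation gate (per second)."""
    E0 = V + 41.0
    if abs(E0) < delta_m:
        alpha = 2000.0
    else:
        alpha = 200.0 * E0 / (1.0 - _exp(-0.1 * E0))
    beta = 8000.0 * _exp(-0.056 * (V + 66.0))
    return alpha, beta


@njit(cache=False)
def h_gate_rates(V):
    """alpha, beta of the sodium inactivation gate (per second)."""
    alpha = 20.0 * _exp(-0.125 * (V + 75.0))
    beta = 2000.0 / (1.0 + 320.0 * _exp(-0.1 * (V + 75.0)))
    return alpha, beta


@njit(cache=False)
def d_gate_rates(V):
    E0 = V + 24.0 - 5.0
    if abs(E0) < 1e-4:
        return 120.0, 120.0
    alpha = 30.0 * E0 / (1.0 - _exp(-E0 / 4.0))
    beta = 12.0 * E0 / (_exp(E0 / 10.0) - 1.0)
    return alpha, beta


@njit(cache=False)
def f_gate_rates(V):
    E0 = V + 34.0
    if abs(E0) < 1e-4:
        alpha = 25.0
    else:
        alpha = 6.25 * E0 / (_exp(E0 / 4.0) - 1.0)
    beta = 12.0 / (1.0 + _exp(-E0 / 4.0))
    return alpha, beta


@njit(cache=False)
def xr1_gate_rates(V):
    alpha = 50.0 / (1.0 + _exp(-(V - 5.0) / 9.0))
    beta = 0.05 * _exp(-(V - 20.0) / 15.0)
    return alpha, beta


@njit(cache=False)
def xr2_gate_rates(V):
    alpha = 50.0 / (1.0 + _exp(-(V - 5.0) / 9.0))
    t = (V + 30.0) / 30.0
    beta = 0.4 * _exp(-(t * t * t))
    return alpha, beta


@njit(cache=False)
def xs_gate_rates(V):
    alpha = 14.0 / (1.0 + _exp(-(V - 40.0) / 9.0))
    beta = 1.0 * _exp(-V / 45.0)
    return alpha, beta


@njit(cache=False)
def s_gate_rates(V):
    alpha = 0.033 * _exp(-V / 17.0)
    beta = 33.0 / (1.0 + _exp(-0.125 * (V + 10.0)))
    return alpha, beta


@njit(cache=False)
def _cell_currents(y, P, cur):
    """Fill ``cur`` (length 17) with the membrane currents of one cell (nA).

    Sign convention: outward positive, inward negative.
    Returns the total ionic current.
    """
    V = y[0]
    m = y[1]
    h = y[2]
    d = y[3]
    f = y[4]
    f2 = y[5]
    f2ds = y[6]
    xr1 = y[7]
    xr2 = y[8]
    xs = y[9]
    s = y[10]
    r = y[11]
    Na_i = max(y[14], 1e-12)
    K_i = max(y[15], 1e-12)
    Ca_i = max(y[16], 1e-12)
    Ca_ds = max(y[17], 1e-12)

    RTF = P[1]
    K_o = P[2]
    Na_o = P[3]
    Ca_o = P[4]

    E_K = RTF * math.log(K_o / K_i)
    # fast-sodium channel reversal: mixed Na/K (P_mh = 0.12) in the
    # reference model; reduces to the pure Nernst potential for P_mh = 0
    E_Na_rev = RTF * math.log((Na_o + P[60] * K_o) / (Na_i + P[60] * K_i))
    E_Na = RTF * math.log(Na_o / Na_i)
    E_Ks = RTF * math.log((K_o + P[13] * Na_o) / (K_i + P[13] * Na_i))

    # inward rectifier: K_o-dependent saturation and steep rectification
    # with half-point 10 mV above E_K and slope RT/2F
    cur[I_K1] = (P[5] * (K_o / (K_o + P[6])) * (V - E_K)
                 / (1.0 + _exp((V - E_K - 10.0) * P[61] / RTF)))

    # fast sodium, G_Na m^3 h (V - E_Na)
    cur[I_NA] = P[7] * (m * m * m) * h * (V - E_Na_rev)
    cur[I_PNA] = P[8] / (1.0 + _exp(-(V + 52.0) / 8.0)) * (V - E_Na_rev)
    cur[I_BNA] = P[9] * (V - E_Na)

    # delayed rectifiers and transient outward
    cur[I_KR] = ((P[10] * xr1 + P[11] * xr2)
                 / (1.0 + _exp((V + 9.0) / 22.4)) * (V - E_K))
    cur[I_KS] = P[12] * xs * xs * (V - E_Ks)
    cur[I_TO] = P[14] * (P[15] + s * (1.0 - P[15])) * r * (V - E_K)

    # L-type calcium current, constant-field form about a +50 mV offset
    FrICa = P[19]
    P_CaL = P[16]
    vs = V - 50.0
    if abs(vs) < 1e-9:
        vs = 1e-9
    u1 = vs / RTF          # single-charge exponent
    u2 = 2.0 * vs / RTF    # divalent exponent
    gate_cyt = d * f * f2
    gate_ds = d * f * f2ds

    ca_flux = (Ca_i * _exp(100.0 / RTF) - Ca_o * _exp(-u2))
    pref_ca = 4.0 * P_CaL * u1 / (1.0 - _exp(-u2))
    cur[I_CAL_CA_CYT] = (1.0 - FrICa) * pref_ca * gate_cyt * ca_flux
    cur[I_CAL_CA_DS] = FrICa * pref_ca * gate_ds * ca_flux

    k_flux = (K_i * _exp(50.0 / RTF) - K_o * _exp(-u1))
    pref_k = P[17] * P_CaL * u1 / (1.0 - _exp(-u1))
    cur[I_CAL_K_CYT] = (1.0 - FrICa) * pref_k * gate_cyt * k_flux
    cur[I_CAL_K_DS] = FrICa * pref_k * gate_ds * k_flux

    na_flux = (Na_i * _exp(50.0 / RTF) - Na_o * _exp(-u1))
    pref_na = P[18] * P_CaL * u1 / (1.0 - _exp(-u1))
    cur[I_CAL_NA_CYT] = (1.0 - FrICa) * pref_na * gate_cyt * na_flux
    cur[I_CAL_NA_DS] = FrICa * pref_na * gate_ds * na_flux

    # background calcium
    E_Ca = 0.5 * RTF * math.log(Ca_o / Ca_i)
    cur[I_BCA] = P[25] * (V - E_Ca)

    # Na/K pump
    cur[I_NAK] = (P[26] * (K_o / (P[27] + K_o)) * (Na_i / (P[28] + Na_i)))

    # Na/Ca exchanger, cytosolic and diadic faces
    k_naca = P[29]
    gama = P[30]
    n_naca = P[31]
    d_naca = P[32]
    fr = P[33]
    na_i_n = Na_i ** n_naca
    na_o_n = Na_o ** n_naca
    e_fwd = _exp(gama * (n_naca - 2.0) * V / RTF)
    e_bwd = _exp((gama - 1.0) * (n_naca - 2.0) * V / RTF)
    num_cyt = e_fwd * na_i_n * Ca_o - e_bwd * na_o_n * Ca_i
    den_cyt = ((1.0 + d_naca * (Ca_i * na_o_n + Ca_o * na_i_n))
               * (1.0 + Ca_i / 0.0069))
    cur[I_NACA_CYT] = (1.0 - fr) * k_naca * num_cyt / den_cyt
    num_ds = e_fwd * na_i_n * Ca_o - e_bwd * na_o_n * Ca_ds
    den_ds = ((1.0 + d_naca * (Ca_ds * na_o_n + Ca_o * na_i_n))
              * (1.0 + Ca_ds / 0.0069))
    cur[I_NACA_DS] = fr * k_naca * num_ds / den_ds

    total = 0.0
    for k in range(N_CURRENTS):
        total += cur[k]
    return total


@njit(cache=False)
def _cell_rhs(y, I_ext, P, dy, cur):
    """Time derivative of one cell's 22 states.

    ``I_ext`` is the total external current into the cell (stimulus plus
    coupling), inward-negative, so C_m dV/dt = -(I_ion + I_ext).
    """
    V = y[0]
    i_ion = _cell_currents(y, P, cur)

    dy[0] = -(i_ion + I_ext) / P[0]

    # gates -------------------------------------------------------------
    a, b = m_gate_rates(V, P[59])
    dy[1] = MS * (a * (1.0 - y[1]) - b * y[1])
    a, b = h_gate_rates(V)
    dy[2] = MS * (a * (1.0 - y[2]) - b * y[2])
    a, b = d_gate_rates(V)
    dy[3] = P[20] * (a * (1.0 - y[3]) - b * y[3])
    a, b = f_gate_rates(V)
    dy[4] = P[21] * (a * (1.0 - y[4]) - b * y[4])

    Ca_i = max(y[16], 1e-12)
    Ca_ds = max(y[17], 1e-12)
    dy[5] = MS * (1.0 - (Ca_i / (P[22] + Ca_i) + y[5]))
    dy[6] = P[24] * (1.0 - (Ca_ds / (P[23] + Ca_ds) + y[6]))

    a, b = xr1_gate_rates(V)
    dy[7] = MS * (a * (1.0 - y[7]) - b * y[7])
    a, b = xr2_gate_rates(V)
    dy[8] = MS * (a * (1.0 - y[8]) - b * y[8])
    a, b = xs_gate_rates(V)
    dy[9] = MS * (a * (1.0 - y[9]) - b * y[9])
    a, b = s_gate_rates(V)
    dy[10] = MS * (a * (1.0 - y[10]) - b * y[10])
    r_inf = 1.0 / (1.0 + _exp(-(V + 4.0) / 5.0))
    dy[11] = MS * 333.0 * (r_inf - y[11])

    # SR release regulation ----------------------------------------------
    cai_reg = Ca_i / (Ca_i + P[42])
    cads_reg = Ca_ds / (Ca_ds + P[43])
    reg = cai_reg + (1.0 - cai_reg) * cads_reg
    act_rate = P[44] * reg * reg
    inact_rate = P[45] + P[44] * reg * reg
    speed_rel = 5.0 if V < -50.0 else 1.0
    prec = 1.0 - y[12] - y[13]
    dy[12] = prec * speed_rel * act_rate - y[12] * speed_rel * inact_rate
    dy[13] = y[12] * speed_rel * inact_rate - speed_rel * P[46] * y[13]

    # SR calcium fluxes (mM/ms) -------------------------------------------
    Ca_up = y[18]
    Ca_rel = y[19]
    K1 = P[34] * P[35] / P[36]
    K2 = Ca_i + Ca_up * K1 + P[34] * P[35] + P[34]
    i_up = Ca_i / K2 * P[37] - Ca_up * K1 / K2 * P[38]
    i_trans = P[41] * (Ca_up - Ca_rel)
    frac = y[12] / (y[12] + 0.25)
    i_rel = (frac * frac * P[39] + P[40]) * Ca_rel

    dy[18] = (P[55] / P[56]) * i_up - i_trans
    dy[19] = (P[56] / P[57]) * i_trans - i_rel

    # cytosolic buffers ----------------------------------------------------
    d_calmod = P[50] * Ca_i * (P[48] - y[20]) - P[51] * y[20]
    d_trop = P[52] * Ca_i * (P[49] - y[21]) - P[53] * y[21]
    dy[20] = d_calmod
    dy[21] = d_trop

    # ion concentrations ---------------------------------------------------
    conv = P[54]  # nA -> mM/ms for a monovalent ion in the cytosol
    dy[14] = -conv * (cur[I_NA] + cur[I_PNA] + cur[I_BNA]
                      + 3.0 * cur[I_NAK]
                      + 3.0 * (cur[I_NACA_CYT] + cur[I_NACA_DS])
                      + cur[I_CAL_NA_CYT] + cur[I_CAL_NA_DS])
    dy[15] = -conv * ((cur[I_K1] + cur[I_KR] + cur[I_KS] + cur[I_TO]
                       + cur[I_CAL_K_CYT] + cur[I_CAL_K_DS])
                      - 2.0 * cur[I_NAK])
    dy[16] = (-(conv / 2.0) * (cur[I_CAL_CA_CYT] + cur[I_BCA]
                               - 2.0 * (cur[I_NACA_CYT] + cur[I_NACA_DS]))
              + Ca_ds * P[58] * P[47]
              + i_rel * (P[57] / P[55])
              - d_calmod - d_trop - i_up)
    dy[17] = -(conv / 2.0) / P[58] * cur[I_CAL_CA_DS] - Ca_ds * P[47]


@njit(cache=False)
def fiber_rhs_flat(y, P, G_gj, stim, dy, scratch):
    """RHS of an N-cell fiber, cell-major flattening, sealed ends.

    ``stim`` is the per-cell external stimulus current (nA, inward
    negative); gap-junction coupling I_gj = G_gj (V_i - V_{i+1}) flows
    between neighbours, with no flux past the first and last cells.
    """
    n = stim.shape[0]
    for i in range(n):
        V_i = y[i * N_STATES]
        coupling_in = 0.0
        if i > 0:
            coupling_in += G_gj * (y[(i - 1) * N_STATES] - V_i)
        if i < n - 1:
            coupling_in -= G_gj * (V_i - y[(i + 1) * N_STATES])
        I_ext = stim[i] - coupling_in
        _cell_rhs(y[i * N_STATES:(i + 1) * N_STATES], I_ext, P,
                  dy[i * N_STATES:(i + 1) * N_STATES], scratch)


@njit(cache=False)
def passive_rhs_flat(y, g_m, E_rest, C_m, G_gj, stim, dy):
    """RHS of a passive (linearised-membrane) fiber.

    The membrane current is exactly g_m (V - E_rest); the 21 non-voltage
    states are carried as frozen constants (zero derivative) so the fiber
    assembly and integrator run bit-identically to the ionic model paths.
    """
    n = stim.shape[0]
    for i in range(n * N_STATES):
        dy[i] = 0.0
    for i in range(n):
        V_i = y[i * N_STATES]
        coupling_in = 0.0
        if i > 0:
            coupling_in += G_gj * (y[(i - 1) * N_STATES] - V_i)
        if i < n - 1:
            coupling_in -= G_gj * (V_i - y[(i + 1) * N_STATES])
        i_ion = g_m * (V_i - E_rest)
        dy[i * N_STATES] = -(i_ion + stim[i] - coupling_in) / C_m
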