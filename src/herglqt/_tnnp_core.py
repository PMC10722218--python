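"""Numerical core of the human ventricular cell model (ten Tusscher 2004
formulation) with the Hodgkin-Huxley I_Kr replaceable by the five-state
Markov chain.

Everything here is implementation detail: voltage-indexed lookup tables for
the gate kinetics and voltage-dependent current factors, and numba kernels
for single cells, 1D strands and 2D sheets.  Hodgkin-Huxley gates advance
with the Rush-Larsen exponential update; intracellular concentrations with
forward Euler (instantaneous-buffer quadratics for Ca); the Markov occupancy
with a truncated-Taylor evaluation of the matrix exponential of Q*dt, which
at the step sizes used here (rate*dt < 1e-2) is the exponential update to
machine precision and conserves total occupancy exactly.

Cell-type indices: 0 = ENDO, 1 = MIDDLE, 2 = EPI.
State-vector layout (one row of 22 doubles per node):
    0 V, 1 m, 2 h, 3 j, 4 d, 5 f, 6 fca, 7 g, 8 r, 9 s, 10 xs,
    11 xr1, 12 xr2, 13 Nai, 14 Ki, 15 Cai, 16 CaSR,
    17 c3, 18 c2, 19 c1, 20 o, 21 i
"""

from __future__ import annotations

import numpy as np
import numba as nb

# ---------------------------------------------------------------------------
# Model constants (ten Tusscher et al. 2004 human ventricular model)
# ---------------------------------------------------------------------------

R = 8314.472          # mJ/(mol K)
T = 310.0             # K
F = 96485.3415        # C/mol
RTONF = R * T / F     # ~26.7137 mV

Ko = 5.4              # mM
Cao = 2.0
Nao = 140.0

Vc = 0.016404         # cytoplasmic volume, uL
Vsr = 0.001094        # SR volume, uL
Bufc = 0.15
Kbufc = 0.001
Bufsr = 10.0
Kbufsr = 0.3
Vmaxup = 0.000425
Kup = 0.00025
CAPACITANCE = 0.185   # uF

GNa = 14.838
GbNa = 0.00029
GCaL = 0.000175
GbCa = 0.000592
GK1 = 5.405
GpCa = 0.825
KpCa = 0.0005
GpK = 0.0146
knak = 1.362
KmK = 1.0
KmNa = 40.0
knaca = 1000.0
KmNai = 87.5
KmCa = 1.38
ksat = 0.1
n_naca = 0.35
pKNa = 0.03
a_rel = 0.016464
b_rel2 = 0.0625       # (0.25)^2
c_rel = 0.008232
V_leak = 0.00008
tau_fca = 2.0
tau_g = 2.0

GKR_HH = 0.096                       # host-model HH I_Kr conductance
GKS_BY_TYPE = (0.245, 0.062, 0.245)  # ENDO, MIDDLE, EPI
GTO_BY_TYPE = (0.073, 0.294, 0.294)

INV_VCF2 = 1.0 / (2.0 * Vc * F)
INV_VCF = 1.0 / (Vc * F)

#: Host-model standard initial conditions (quiescent).
INITIAL_STATE = np.array(
    [
        -86.2,    # V
        0.0,      # m
        0.75,     # h
        0.75,     # j
        0.0,      # d
        1.0,      # f
        1.0,      # fca
        1.0,      # g
        0.0,      # r
        1.0,      # s
        0.0,      # xs
        0.0,      # xr1
        1.0,      # xr2
        11.6,     # Nai
        138.3,    # Ki
        0.0002,   # Cai
        0.2,      # CaSR
        1.0, 0.0, 0.0, 0.0, 0.0,   # MC occupancy (all in C3)
    ]
)

NSTATE = 22

# ---------------------------------------------------------------------------
# Lookup-table grids
# ---------------------------------------------------------------------------

V_MIN, V_MAX, DVTAB = -120.0, 90.0, 0.01
NV = int(round((V_MAX - V_MIN) / DVTAB)) + 1
INV_DV = 1.0 / DVTAB

U_MIN, U_MAX, DUTAB = -80.0, 240.0, 0.01   # grid in (V - EK) for I_K1
NU = int(round((U_MAX - U_MIN) / DUTAB)) + 1
INV_DU = 1.0 / DUTAB

CAI_MIN, CAI_MAX, DCAI = 0.0, 0.02, 2e-6
NCAI = int(round((CAI_MAX - CAI_MIN) / DCAI)) + 1
INV_DCAI = 1.0 / DCAI

# Row indices into the voltage table
(
    R_MINF, R_MRL, R_HINF, R_HRL, R_JINF, R_JRL, R_DINF, R_DRL,
    R_FINF, R_FRL, R_RINF, R_RRL, R_XSINF, R_XSRL, R_XR1INF, R_XR1RL,
    R_XR2INF, R_XR2RL, R_SEINF, R_SERL, R_SNINF, R_SNRL,
    R_ICALA, R_ICALB, R_INACAC, R_INACAD, R_INAKF, R_IPKR,
) = range(28)
NROWS = 28


def build_voltage_tables(dt: float) -> np.ndarray:
    """Voltage-dependent gate targets/Rush-Larsen factors and current factors.

    Returns an array of shape (28, NV); Rush-Larsen rows hold exp(-dt/tau).
    """
    V = V_MIN + DVTAB * np.arange(NV)
    tab = np.empty((NROWS, NV))

    # m gate
    am = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) + 0.10 / (1.0 + np.exp((V - 50.0) / 200.0))
    tab[R_MINF] = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    tab[R_MRL] = np.exp(-dt / (am * bm))

    # h gate
    tab[R_HINF] = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    ah = np.where(V >= -40.0, 0.0, 0.057 * np.exp(-(V + 80.0) / 6.8))
    bh = np.where(
        V >= -40.0,
        0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1))),
        2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V),
    )
    tab[R_HRL] = np.exp(-dt * (ah + bh))

    # j gate
    tab[R_JINF] = tab[R_HINF]
    aj = np.where(
        V >= -40.0,
        0.0,
        (-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
        * (V + 37.78)
        / (1.0 + np.exp(0.311 * (V + 79.23))),
    )
    bj = np.where(
        V >= -40.0,
        0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0))),
        0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14))),
    )
    tab[R_JRL] = np.exp(-dt * (aj + bj))

    # d gate
    tab[R_DINF] = 1.0 / (1.0 + np.exp((-5.0 - V) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
    cd = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
    tab[R_DRL] = np.exp(-dt / (ad * bd + cd))

    # f gate
    tab[R_FINF] = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tau_f = 1125.0 * np.exp(-((V + 27.0) ** 2) / 240.0) + 80.0 + 165.0 / (
        1.0 + np.exp((25.0 - V) / 10.0)
    )
    tab[R_FRL] = np.exp(-dt / tau_f)

    # r gate (transient outward activation)
    tab[R_RINF] = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    tau_r = 9.5 * np.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8
    tab[R_RRL] = np.exp(-dt / tau_r)

    # xs gate
    tab[R_XSINF] = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    axs = 1100.0 / np.sqrt(1.0 + np.exp((-10.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + np.exp((V - 60.0) / 20.0))
    tab[R_XSRL] = np.exp(-dt / (axs * bxs))

    # HH I_Kr gates (kept for the host model's native formulation)
    tab[R_XR1INF] = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    axr1 = 450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + np.exp((V + 30.0) / 11.5))
    tab[R_XR1RL] = np.exp(-dt / (axr1 * bxr1))
    tab[R_XR2INF] = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + np.exp((V - 60.0) / 20.0))
    tab[R_XR2RL] = np.exp(-dt / (axr2 * bxr2))

    # s gate, epicardial/mid variant
    tab[R_SEINF] = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
    tau_se = 85.0 * np.exp(-((V + 45.0) ** 2) / 320.0) + 5.0 / (
        1.0 + np.exp((V - 20.0) / 5.0)
    ) + 3.0
    tab[R_SERL] = np.exp(-dt / tau_se)
    # s gate, endocardial variant
    tab[R_SNINF] = 1.0 / (1.0 + np.exp((V + 28.0) / 5.0))
    tau_sn = 1000.0 * np.exp(-((V + 67.0) ** 2) / 1000.0) + 8.0
    tab[R_SNRL] = np.exp(-dt / tau_sn)

    # I_CaL voltage factors: ICaL = d*f*fca*(A(V)*Cai - B(V))
    Vsafe = np.where(np.abs(V) < 1e-6, 1e-6, V)
    z = 2.0 * Vsafe * F / (R * T)
    ez = np.exp(z)
    pref = GCaL * 4.0 * Vsafe * F * F / (R * T) / (ez - 1.0)
    tab[R_ICALA] = pref * ez
    tab[R_ICALB] = pref * 0.341 * Cao

    # I_NaCa voltage factors: INaCa = C(V)*Nai^3 - D(V)*Cai
    den = (KmNai**3 + Nao**3) * (KmCa + Cao) * (
        1.0 + ksat * np.exp((n_naca - 1.0) * V * F / (R * T))
    )
    tab[R_INACAC] = knaca * np.exp(n_naca * V * F / (R * T)) * Cao / den
    tab[R_INACAD] = knaca * np.exp((n_naca - 1.0) * V * F / (R * T)) * Nao**3 * 2.5 / den

    # I_NaK voltage factor (full current = factor * Nai/(Nai+KmNa))
    rec_inak = 1.0 / (
        1.0 + 0.1245 * np.exp(-0.1 * V * F / (R * T)) + 0.0353 * np.exp(-V * F / (R * T))
    )
    tab[R_INAKF] = knak * (Ko / (Ko + KmK)) * rec_inak

    # I_pK rectification
    tab[R_IPKR] = 1.0 / (1.0 + np.exp((25.0 - V) / 5.98))

    return np.ascontiguousarray(tab.T)  # (NV, NROWS): one voltage's entries are contiguous


def build_ik1_table() -> np.ndarray:
    """Inward-rectifier open fraction as a function of u = V - EK."""
    u = U_MIN + DUTAB * np.arange(NU)
    ak1 = 0.1 / (1.0 + np.exp(0.06 * (u - 200.0)))
    bk1 = (3.0 * np.exp(0.0002 * (u + 100.0)) + np.exp(0.1 * (u - 10.0))) / (
        1.0 + np.exp(-0.5 * u)
    )
    return np.ascontiguousarray(ak1 / (ak1 + bk1))


def build_calcium_tables() -> tuple:
    """fCa and g gate targets as functions of Cai (mM)."""
    cai = CAI_MIN + DCAI * np.arange(NCAI)
    cai_s = np.maximum(cai, 1e-12)
    alpha = 1.0 / (1.0 + (cai_s / 0.000325) ** 8)
    beta = 0.1 / (1.0 + np.exp((cai_s - 0.0005) / 0.0001))
    gama = 0.2 / (1.0 + np.exp((cai_s - 0.00075) / 0.0008))
    fca_inf = (alpha + beta + gama + 0.23) / 1.46
    g_inf = np.where(
        cai_s < 0.00035,
        1.0 / (1.0 + (cai_s / 0.00035) ** 6),
        1.0 / (1.0 + (cai_s / 0.00035) ** 16),
    )
    return np.ascontiguousarray(fca_inf), np.ascontiguousarray(g_inf)


def build_mc_rate_tables(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-transition rate tables r_k(V) = a_k exp(b_k V), shape (8, NV)."""
    V = V_MIN + DVTAB * np.arange(NV)
    rates = np.asarray(a)[:, None] * np.exp(np.asarray(b)[:, None] * V[None, :])
    return np.ascontiguousarray(rates.T)  # (NV, 8)


class Tables:
    """Bundle of lookup tables for a given time step."""

    def __init__(self, dt: float, mc_a: np.ndarray, mc_b: np.ndarray):
        self.dt = float(dt)
        self.vtab = build_voltage_tables(dt)
        self.ik1 = build_ik1_table()
        self.fca_inf, self.g_inf = build_calcium_tables()
        self.mcr = build_mc_rate_tables(mc_a, mc_b)
        self.e_fcag = float(np.exp(-dt / tau_fca))


_table_cache: dict = {}


def get_tables(dt: float, mc_a: np.ndarray, mc_b: np.ndarray) -> Tables:
    key = (round(float(dt), 12), tuple(np.round(mc_a, 15)), tuple(np.round(mc_b, 15)))
    tb = _table_cache.get(key)
    if tb is None:
        tb = Tables(dt, mc_a, mc_b)
        if len(_table_cache) > 16:
            _table_cache.clear()
        _table_cache[key] = tb
    return tb


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

@nb.njit(inline="always")
def _clip_idx(x, x0, inv_dx, n):
    k = int((x - x0) * inv_dx + 0.5)
    if k < 0:
        k = 0
    elif k >= n:
        k = n - 1
    return k


@nb.njit(inline="always", fastmath=True)
def _reversals(S, i, E):
    """Refresh the cached Nernst potentials (Ek, Ena, Eks, Eca) of node i."""
    E[i, 0] = RTONF * np.log(Ko / S[i, 14])
    E[i, 1] = RTONF * np.log(Nao / S[i, 13])
    E[i, 2] = RTONF * np.log((Ko + pKNa * Nao) / (S[i, 14] + pKNa * S[i, 13]))
    E[i, 3] = 0.5 * RTONF * np.log(Cao / S[i, 15])


@nb.njit(inline="always", fastmath=True)
def _node_update(S, i, ctype, gkr_eff, dt, vtab, ik1tab, fcat, gtab, mcr,
                 e_fcag, use_mc, E):
    """Advance gates/concentrations/occupancies of node i; return currents.

    The membrane potential itself is NOT updated (the caller adds reaction
    and diffusion terms).  Returns (Iion, IKr, INa, ICaL, IKs, IK1, Ito).
    Currents are computed from the pre-update state, matching the reference
    integration order of the host model.  ``E`` caches the four Nernst
    potentials per node; callers refresh it via ``_reversals`` (tissue
    kernels refresh every few steps — the concentrations they depend on
    drift far more slowly than that).
    """
    V = S[i, 0]
    m = S[i, 1]
    h = S[i, 2]
    j = S[i, 3]
    d = S[i, 4]
    f = S[i, 5]
    fca = S[i, 6]
    g = S[i, 7]
    r = S[i, 8]
    s = S[i, 9]
    xs = S[i, 10]
    xr1 = S[i, 11]
    xr2 = S[i, 12]
    Nai = S[i, 13]
    Ki = S[i, 14]
    Cai = S[i, 15]
    CaSR = S[i, 16]

    kV = _clip_idx(V, V_MIN, INV_DV, NV)

    Ek = E[i, 0]
    Ena = E[i, 1]
    Eks = E[i, 2]
    Eca = E[i, 3]

    if ctype == 0:
        gks = 0.245
        gto = 0.073
    elif ctype == 1:
        gks = 0.062
        gto = 0.294
    else:
        gks = 0.245
        gto = 0.294

    INa = GNa * m * m * m * h * j * (V - Ena)
    ICaL = d * f * fca * (vtab[kV, R_ICALA] * Cai - vtab[kV, R_ICALB])
    Ito = gto * r * s * (V - Ek)
    IKs = gks * xs * xs * (V - Eks)
    if use_mc == 1:
        IKr = gkr_eff * S[i, 20] * (V - Ek)
    else:
        IKr = gkr_eff * xr1 * xr2 * (V - Ek)
    kU = _clip_idx(V - Ek, U_MIN, INV_DU, NU)
    IK1 = GK1 * ik1tab[kU] * (V - Ek)
    INaCa = vtab[kV, R_INACAC] * Nai * Nai * Nai - vtab[kV, R_INACAD] * Cai
    INaK = vtab[kV, R_INAKF] * Nai / (Nai + KmNa)
    IpCa = GpCa * Cai / (KpCa + Cai)
    IpK = GpK * vtab[kV, R_IPKR] * (V - Ek)
    IbNa = GbNa * (V - Ena)
    IbCa = GbCa * (V - Eca)

    Iion = IKr + IKs + IK1 + Ito + INa + IbNa + ICaL + IbCa + INaK + INaCa + IpCa + IpK

    # --- calcium dynamics (instantaneous buffering) ---
    CaCurrent = -(ICaL + IbCa + IpCa - 2.0 * INaCa) * INV_VCF2 * CAPACITANCE
    A = a_rel * CaSR * CaSR / (b_rel2 + CaSR * CaSR) + c_rel
    Irel = A * d * g
    Ileak = V_leak * (CaSR - Cai)
    SERCA = Vmaxup / (1.0 + (Kup * Kup) / (Cai * Cai))
    CaSRCurrent = SERCA - Irel - Ileak

    CaCSQN = Bufsr * CaSR / (CaSR + Kbufsr)
    dCaSR = dt * (Vc / Vsr) * CaSRCurrent
    bjsr = Bufsr - CaCSQN - dCaSR - CaSR + Kbufsr
    cjsr = Kbufsr * (CaCSQN + dCaSR + CaSR)
    S[i, 16] = (np.sqrt(bjsr * bjsr + 4.0 * cjsr) - bjsr) / 2.0

    CaBuf = Bufc * Cai / (Cai + Kbufc)
    dCai = dt * (CaCurrent - CaSRCurrent)
    bc = Bufc - CaBuf - dCai - Cai + Kbufc
    cc = Kbufc * (CaBuf + dCai + Cai)
    S[i, 15] = (np.sqrt(bc * bc + 4.0 * cc) - bc) / 2.0

    S[i, 13] = Nai + dt * (-(INa + IbNa + 3.0 * INaK + 3.0 * INaCa) * INV_VCF * CAPACITANCE)
    S[i, 14] = Ki + dt * (-(IK1 + Ito + IKr + IKs - 2.0 * INaK + IpK) * INV_VCF * CAPACITANCE)

    # --- Rush-Larsen gate updates ---
    S[i, 1] = vtab[kV, R_MINF] - (vtab[kV, R_MINF] - m) * vtab[kV, R_MRL]
    S[i, 2] = vtab[kV, R_HINF] - (vtab[kV, R_HINF] - h) * vtab[kV, R_HRL]
    S[i, 3] = vtab[kV, R_JINF] - (vtab[kV, R_JINF] - j) * vtab[kV, R_JRL]
    S[i, 4] = vtab[kV, R_DINF] - (vtab[kV, R_DINF] - d) * vtab[kV, R_DRL]
    S[i, 5] = vtab[kV, R_FINF] - (vtab[kV, R_FINF] - f) * vtab[kV, R_FRL]
    S[i, 8] = vtab[kV, R_RINF] - (vtab[kV, R_RINF] - r) * vtab[kV, R_RRL]
    if ctype == 0:
        S[i, 9] = vtab[kV, R_SNINF] - (vtab[kV, R_SNINF] - s) * vtab[kV, R_SNRL]
    else:
        S[i, 9] = vtab[kV, R_SEINF] - (vtab[kV, R_SEINF] - s) * vtab[kV, R_SERL]
    S[i, 10] = vtab[kV, R_XSINF] - (vtab[kV, R_XSINF] - xs) * vtab[kV, R_XSRL]
    S[i, 11] = vtab[kV, R_XR1INF] - (vtab[kV, R_XR1INF] - xr1) * vtab[kV, R_XR1RL]
    S[i, 12] = vtab[kV, R_XR2INF] - (vtab[kV, R_XR2INF] - xr2) * vtab[kV, R_XR2RL]

    # calcium-gated gates with their voltage-conditional freeze
    kC = _clip_idx(Cai, CAI_MIN, INV_DCAI, NCAI)
    fca_inf = fcat[kC]
    fca_new = fca_inf - (fca_inf - fca) * e_fcag
    if not (fca_new > fca and V > -60.0):
        S[i, 6] = fca_new
    g_inf = gtab[kC]
    g_new = g_inf - (g_inf - g) * e_fcag
    if not (g_new > g and V > -60.0):
        S[i, 7] = g_new

    # --- Markov occupancy: truncated-Taylor matrix exponential (order 4) ---
    if use_mc == 1:
        r0 = mcr[kV, 0]
        r1 = mcr[kV, 1]
        r2 = mcr[kV, 2]
        r3 = mcr[kV, 3]
        r4 = mcr[kV, 4]
        r5 = mcr[kV, 5]
        r6 = mcr[kV, 6]
        r7 = mcr[kV, 7]
        p0 = S[i, 17]
        p1 = S[i, 18]
        p2 = S[i, 19]
        p3 = S[i, 20]
        p4 = S[i, 21]
        y0 = p0
        y1 = p1
        y2 = p2
        y3 = p3
        y4 = p4
        for order in range(1, 5):
            z0 = dt * (-r0 * y0 + r1 * y1) / order
            z1 = dt * (r0 * y0 - (r1 + r2) * y1 + r3 * y2) / order
            z2 = dt * (r2 * y1 - (r3 + r4) * y2 + r5 * y3) / order
            z3 = dt * (r4 * y2 - (r5 + r6) * y3 + r7 * y4) / order
            z4 = dt * (r6 * y3 - r7 * y4) / order
            p0 += z0
            p1 += z1
            p2 += z2
            p3 += z3
            p4 += z4
            y0 = z0
            y1 = z1
            y2 = z2
            y3 = z3
            y4 = z4
        S[i, 17] = p0
        S[i, 18] = p1
        S[i, 19] = p2
        S[i, 20] = p3
        S[i, 21] = p4

    return Iion, IKr, INa, ICaL, IKs, IK1, Ito


@nb.njit(cache=True, fastmath=True)
def run_cell(S, ctype, gkr_eff, dt, n_steps, stim_start, stim_dur, stim_amp,
             vtab, ik1tab, fcat, gtab, mcr, e_fcag, use_mc,
             Vrec, IKrrec, INarec, ICaLrec, IKsrec, IK1rec, Itorec):
    """Advance one cell n_steps; record V and major currents each step.

    Vrec must have length n_steps + 1 (includes the final state); current
    records have length n_steps (evaluated at the pre-step state).
    Reversal potentials are refreshed every step.
    """
    E = np.empty((1, 4))
    for step in range(n_steps):
        Vrec[step] = S[0, 0]
        _reversals(S, 0, E)
        istim = stim_amp if (stim_start <= step < stim_start + stim_dur) else 0.0
        Iion, ikr, ina, ical, iks, ik1, ito = _node_update(
            S, 0, ctype, gkr_eff, dt, vtab, ik1tab, fcat, gtab, mcr, e_fcag, use_mc, E
        )
        S[0, 0] -= dt * (Iion + istim)
        IKrrec[step] = ikr
        INarec[step] = ina
        ICaLrec[step] = ical
        IKsrec[step] = iks
        IK1rec[step] = ik1
        Itorec[step] = ito
    Vrec[n_steps] = S[0, 0]


@nb.njit(cache=True, fastmath=True)
def run_strand(S, ctype, gkr_eff, D, dx, dt, n_steps,
               stim_start, stim_dur, stim_lo, stim_hi, stim_amp,
               vtab, ik1tab, fcat, gtab, mcr, e_fcag, use_mc,
               rec_every, Vrec, rev_every=5):
    """Monodomain cable with explicit diffusion and no-flux ends.

    Stimuli are given as parallel arrays (start step, duration in steps,
    node range inclusive, amplitude pA/pF).  V is recorded every
    ``rec_every`` steps into Vrec[frame, node]; frame k corresponds to time
    k * rec_every * dt (the pre-step state).
    """
    N = S.shape[0]
    n_stim = stim_start.shape[0]
    lap = np.empty(N)
    E = np.empty((N, 4))
    for i in range(N):
        _reversals(S, i, E)
    coef = D / (dx * dx)
    frame = 0
    for step in range(n_steps):
        if step % rev_every == 0:
            for i in range(N):
                _reversals(S, i, E)
        if step % rec_every == 0 and frame < Vrec.shape[0]:
            for i in range(N):
                Vrec[frame, i] = S[i, 0]
            frame += 1
        for i in range(N):
            vm = S[i, 0]
            vl = S[i - 1, 0] if i > 0 else S[i + 1, 0]
            vr = S[i + 1, 0] if i < N - 1 else S[i - 1, 0]
            lap[i] = coef * (vl - 2.0 * vm + vr)
        for i in range(N):
            istim = 0.0
            for ss in range(n_stim):
                if (stim_start[ss] <= step < stim_start[ss] + stim_dur[ss]
                        and stim_lo[ss] <= i <= stim_hi[ss]):
                    istim += stim_amp[ss]
            Iion, ikr, ina, ical, iks, ik1, ito = _node_update(
                S, i, ctype[i], gkr_eff[i], dt, vtab, ik1tab, fcat, gtab, mcr,
                e_fcag, use_mc, E
            )
            S[i, 0] += dt * (lap[i] - Iion - istim)
    return frame


@nb.njit(cache=True, fastmath=True)
def run_sheet(S, ctype, gkr_eff, nx, ny, D, dx, dt, n_steps, step_offset,
              stim_start, stim_dur, stim_x0, stim_x1, stim_y0, stim_y1, stim_amp,
              vtab, ik1tab, fcat, gtab, mcr, e_fcag, use_mc,
              frame_every, Vframes, probe_idx, probe_every, probe_rec,
              rev_every=10):
    """Isotropic monodomain sheet (5-point Laplacian, no-flux boundaries).

    The state S is flattened row-major: node (ix, iy) -> i = iy * nx + ix.
    Stimulus rectangles are inclusive node ranges.  ``step_offset`` shifts
    the stimulus clock so a run can be split into stages.  Frames are stored
    every ``frame_every`` steps; probe voltages every ``probe_every`` steps.
    Returns (frames_written, probe_samples_written).
    """
    N = nx * ny
    n_stim = stim_start.shape[0]
    lap = np.empty(N)
    E = np.empty((N, 4))
    for i in range(N):
        _reversals(S, i, E)
    coef = D / (dx * dx)
    frame = 0
    psample = 0
    n_probe = probe_idx.shape[0]
    for step in range(n_steps):
        gstep = step + step_offset
        if step % rev_every == 0:
            for i in range(N):
                _reversals(S, i, E)
        if frame_every > 0 and step % frame_every == 0 and frame < Vframes.shape[0]:
            for i in range(N):
                Vframes[frame, i] = S[i, 0]
            frame += 1
        if probe_every > 0 and step % probe_every == 0 and psample < probe_rec.shape[0]:
            for p in range(n_probe):
                probe_rec[psample, p] = S[probe_idx[p], 0]
            psample += 1
        for iy in range(ny):
            base = iy * nx
            up = base - nx if iy > 0 else base + nx
            dn = base + nx if iy < ny - 1 else base - nx
            for ix in range(nx):
                i = base + ix
                vm = S[i, 0]
                vl = S[i - 1, 0] if ix > 0 else S[i + 1, 0]
                vr = S[i + 1, 0] if ix < nx - 1 else S[i - 1, 0]
                vu = S[up + ix, 0]
                vd = S[dn + ix, 0]
                lap[i] = coef * (vl + vr + vu + vd - 4.0 * vm)
        any_stim = False
        for ss in range(n_stim):
            if stim_start[ss] <= gstep < stim_start[ss] + stim_dur[ss]:
                any_stim = True
        for iy in range(ny):
            for ix in range(nx):
                i = iy * nx + ix
                istim = 0.0
                if any_stim:
                    for ss in range(n_stim):
                        if (stim_start[ss] <= gstep < stim_start[ss] + stim_dur[ss]
                                and stim_x0[ss] <= ix <= stim_x1[ss]
                                and stim_y0[ss] <= iy <= stim_y1[ss]):
                            istim += stim_amp[ss]
                Iion, ikr, ina, ical, iks, ik1, ito = _node_update(
                    S, i, ctype[i], gkr_eff[i], dt, vtab, ik1tab, fcat, gtab,
                    mcr, e_fcag, use_mc, E
                )
                S[i, 0] += dt * (lap[i] - Iion - istim)
    return frame, psample
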