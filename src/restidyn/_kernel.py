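"""Compiled numerical core: TP06 right-hand side and beat-driven integrator.

The integrator advances the model with the operator-split scheme the model's
original authors used for this stiff system: exponential (Rush-Larsen)
updates for the 13 relaxation variables and forward Euler for membrane
potential and concentrations, at a fixed 0.02 ms step.  Beat bookkeeping
(stimulus injection, upstroke detection, APD_-60mV measurement, capture
classification, optional trace sampling and current clamping) happens
in-line so that thousand-beat pacing trains run in seconds.

Everything here is deterministic: fixed step, fixed evaluation order, no
fastmath reassociation.
"""

import math

import numpy as np
from numba import njit

# Layout of the scratch/output vector filled by tp06_eval:
#   [0:19)   time-derivatives of the 19 states
#   [19:32)  steady-state values (inf) of the 13 relaxation variables
#   [32:45)  time constants (tau, ms) of the 13 relaxation variables
#   [45:57)  membrane currents (A/F), order:
#            I_CaL, I_Kr, I_Ks, I_Na, I_K1, I_to, I_NaCa, I_NaK,
#            I_pCa, I_pK, I_bNa, I_bCa
INF_OFF = 19
TAU_OFF = 32
CUR_OFF = 45
EVAL_LEN = 57

MAX_COEF = 16  # clamp polynomial coefficients (supports order <= 15)

#: kernel slot for each clampable current
CLAMP_INDEX = {"I_CaL": 0, "I_Kr": 1, "I_Ks": 2}

# Parameter vector indices (see tp06.PARAM_NAMES).
(_G_NA, _G_K1, _G_TO, _G_KR, _G_KS, _G_CAL, _G_BNA, _G_BCA, _G_PCA, _G_PK,
 _P_NAK, _K_NACA, _VMAX_UP, _V_REL, _V_LEAK, _V_XFER, _NA_O, _K_O, _CA_O,
 _K_MK, _K_MNA, _K_MNAI, _K_MCA, _K_SAT, _GAMMA, _K_PCA, _K1P, _K2P, _K3,
 _K4, _EC, _MAXSR, _MINSR, _BUFC, _KBUFC, _BUFSR, _KBUFSR, _BUFSS, _KBUFSS,
 _V_C, _V_SR, _V_SS, _CM, _F, _R, _T, _P_KNA, _K_UP) = range(48)


@njit(cache=True)
def _polyval_clipped(coefs, n, vlo, vhi, v):
    """Evaluate a low->high coefficient polynomial at V clipped to its fit
    range (boundary value outside the range, no extrapolation)."""
    if v < vlo:
        v = vlo
    elif v > vhi:
        v = vhi
    acc = 0.0
    for i in range(n - 1, -1, -1):
        acc = acc * v + coefs[i]
    return acc


@njit(cache=True)
def tp06_eval(y, p, i_stim, clamp_now, coefs, ncoef, vlo, vhi, out):
    """Fill ``out`` with derivatives, gate inf/tau values and currents.

    ``clamp_now`` holds 0/1 flags (slots: I_CaL, I_Kr, I_Ks) saying whether
    the fitted voltage-polynomial replaces the native current *at this
    instant* (blanking is resolved by the caller).
    """
    V = y[0]
    Xr1 = y[1]; Xr2 = y[2]; Xs = y[3]
    m = y[4]; h = y[5]; j = y[6]
    d = y[7]; f = y[8]; f2 = y[9]; fCass = y[10]
    s = y[11]; r = y[12]; Rbar = y[13]
    Cai = y[14]; CaSR = y[15]; Cass = y[16]
    Nai = y[17]; Ki = y[18]

    F = p[_F]; Rgas = p[_R]; T = p[_T]
    RTONF = Rgas * T / F
    FONRT = 1.0 / RTONF

    Ko = p[_K_O]; Nao = p[_NA_O]; Cao = p[_CA_O]

    Ek = RTONF * math.log(Ko / Ki)
    Ena = RTONF * math.log(Nao / Nai)
    Eks = RTONF * math.log((Ko + p[_P_KNA] * Nao) / (Ki + p[_P_KNA] * Nai))
    Eca = 0.5 * RTONF * math.log(Cao / Cai)

    # --- fast Na+ current ---
    INa = p[_G_NA] * m * m * m * h * j * (V - Ena)

    # --- L-type Ca2+ current (GHK-like driving term, V shifted by 15 mV) ---
    if clamp_now[0] == 1:
        ICaL = _polyval_clipped(coefs[0], ncoef[0], vlo[0], vhi[0], V)
    else:
        if abs(V - 15.0) < 1e-6:
            # limit of 4(V-15)F^2/RT / (exp(2(V-15)F/RT)-1) -> 2F
            ICaL = p[_G_CAL] * d * f * f2 * fCass * 2.0 * F * \
                (0.25 * Cass - Cao)
        else:
            expv = math.exp(2.0 * (V - 15.0) * FONRT)
            ICaL = p[_G_CAL] * d * f * f2 * fCass * 4.0 * (V - 15.0) * F * FONRT * \
                (0.25 * Cass * expv - Cao) / (expv - 1.0)

    # --- delayed rectifiers ---
    if clamp_now[1] == 1:
        IKr = _polyval_clipped(coefs[1], ncoef[1], vlo[1], vhi[1], V)
    else:
        IKr = p[_G_KR] * math.sqrt(Ko / 5.4) * Xr1 * Xr2 * (V - Ek)
    if clamp_now[2] == 1:
        IKs = _polyval_clipped(coefs[2], ncoef[2], vlo[2], vhi[2], V)
    else:
        IKs = p[_G_KS] * Xs * Xs * (V - Eks)

    # --- inward rectifier ---
    Ak1 = 0.1 / (1.0 + math.exp(0.06 * (V - Ek - 200.0)))
    Bk1 = (3.0 * math.exp(0.0002 * (V - Ek + 100.0)) +
           math.exp(0.1 * (V - Ek - 10.0))) / (1.0 + math.exp(-0.5 * (V - Ek)))
    IK1 = p[_G_K1] * Ak1 / (Ak1 + Bk1) * (V - Ek)

    # --- transient outward ---
    Ito = p[_G_TO] * r * s * (V - Ek)

    # --- Na+/Ca2+ exchanger ---
    gam = p[_GAMMA]
    eg = math.exp(gam * V * FONRT)
    eg1 = math.exp((gam - 1.0) * V * FONRT)
    INaCa = p[_K_NACA] * (eg * Nai * Nai * Nai * Cao -
                          eg1 * Nao * Nao * Nao * Cai * 2.5) / \
        ((p[_K_MNAI] ** 3 + Nao ** 3) * (p[_K_MCA] + Cao) *
         (1.0 + p[_K_SAT] * eg1))

    # --- Na+/K+ pump ---
    INaK = p[_P_NAK] * Ko / (Ko + p[_K_MK]) * Nai / (Nai + p[_K_MNA]) / \
        (1.0 + 0.1245 * math.exp(-0.1 * V * FONRT) +
         0.0353 * math.exp(-V * FONRT))

    # --- sarcolemmal Ca2+ pump, plateau K+, backgrounds ---
    IpCa = p[_G_PCA] * Cai / (p[_K_PCA] + Cai)
    IpK = p[_G_PK] * (V - Ek) / (1.0 + math.exp((25.0 - V) / 5.98))
    IbNa = p[_G_BNA] * (V - Ena)
    IbCa = p[_G_BCA] * (V - Eca)

    Iion = INa + IK1 + Ito + IKr + IKs + ICaL + INaCa + INaK + IpCa + IpK + \
        IbNa + IbCa

    # --- gate kinetics ---
    # I_Kr activation Xr1
    xr1_inf = 1.0 / (1.0 + math.exp((-26.0 - V) / 7.0))
    a = 450.0 / (1.0 + math.exp((-45.0 - V) / 10.0))
    b = 6.0 / (1.0 + math.exp((V + 30.0) / 11.5))
    tau_xr1 = a * b
    # I_Kr inactivation Xr2
    xr2_inf = 1.0 / (1.0 + math.exp((V + 88.0) / 24.0))
    a = 3.0 / (1.0 + math.exp((-60.0 - V) / 20.0))
    b = 1.12 / (1.0 + math.exp((V - 60.0) / 20.0))
    tau_xr2 = a * b
    # I_Ks activation Xs
    xs_inf = 1.0 / (1.0 + math.exp((-5.0 - V) / 14.0))
    a = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - V) / 6.0))
    b = 1.0 / (1.0 + math.exp((V - 35.0) / 15.0))
    tau_xs = a * b + 80.0
    # I_Na activation m
    m_inf = 1.0 / ((1.0 + math.exp((-56.86 - V) / 9.03)) ** 2)
    a = 1.0 / (1.0 + math.exp((-60.0 - V) / 5.0))
    b = 0.1 / (1.0 + math.exp((V + 35.0) / 5.0)) + \
        0.1 / (1.0 + math.exp((V - 50.0) / 200.0))
    tau_m = a * b
    # I_Na inactivation h
    h_inf = 1.0 / ((1.0 + math.exp((V + 71.55) / 7.43)) ** 2)
    if V >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
    else:
        ah = 0.057 * math.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.3485 * V)
    tau_h = 1.0 / (ah + bh)
    # I_Na inactivation j
    j_inf = h_inf
    if V >= -40.0:
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
    else:
        aj = (-2.5428e4 * math.exp(0.2444 * V) -
              6.948e-6 * math.exp(-0.04391 * V)) * (V + 37.78) / \
            (1.0 + math.exp(0.311 * (V + 79.23)))
        bj = 0.02424 * math.exp(-0.01052 * V) / \
            (1.0 + math.exp(-0.1378 * (V + 40.14)))
    tau_j = 1.0 / (aj + bj)
    # I_CaL activation d
    d_inf = 1.0 / (1.0 + math.exp((-8.0 - V) / 7.5))
    a = 1.4 / (1.0 + math.exp((-35.0 - V) / 13.0)) + 0.25
    b = 1.4 / (1.0 + math.exp((V + 5.0) / 5.0))
    c = 1.0 / (1.0 + math.exp((50.0 - V) / 20.0))
    tau_d = a * b + c
    # I_CaL voltage inactivation f
    f_inf = 1.0 / (1.0 + math.exp((V + 20.0) / 7.0))
    tau_f = 1102.5 * math.exp(-((V + 27.0) ** 2) / 225.0) + \
        200.0 / (1.0 + math.exp((13.0 - V) / 10.0)) + \
        180.0 / (1.0 + math.exp((V + 30.0) / 10.0)) + 20.0
    # I_CaL voltage inactivation f2
    f2_inf = 0.67 / (1.0 + math.exp((V + 35.0) / 7.0)) + 0.33
    tau_f2 = 562.0 * math.exp(-((V + 27.0) ** 2) / 240.0) + \
        31.0 / (1.0 + math.exp((25.0 - V) / 10.0)) + \
        80.0 / (1.0 + math.exp((V + 30.0) / 10.0))
    # I_CaL Ca-dependent inactivation fCass (function of subspace Ca2+)
    cs2 = (Cass / 0.05) ** 2
    fcass_inf = 0.6 / (1.0 + cs2) + 0.4
    tau_fcass = 80.0 / (1.0 + cs2) + 2.0
    # I_to inactivation s (epicardial kinetics)
    s_inf = 1.0 / (1.0 + math.exp((V + 20.0) / 5.0))
    tau_s = 85.0 * math.exp(-((V + 45.0) ** 2) / 320.0) + \
        5.0 / (1.0 + math.exp((V - 20.0) / 5.0)) + 3.0
    # I_to activation r
    r_inf = 1.0 / (1.0 + math.exp((20.0 - V) / 6.0))
    tau_r = 9.5 * math.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8

    # --- SR Ca2+ release (CICR) ---
    kcasr = p[_MAXSR] - (p[_MAXSR] - p[_MINSR]) / \
        (1.0 + (p[_EC] / CaSR) ** 2)
    k1 = p[_K1P] / kcasr
    k2 = p[_K2P] * kcasr
    # RyR availability R' relaxes to k4/(k4 + k2*Cass) with rate k4+k2*Cass
    rbar_rate = p[_K4] + k2 * Cass
    rbar_inf = p[_K4] / rbar_rate
    tau_rbar = 1.0 / rbar_rate
    O = k1 * Cass * Cass * Rbar / (p[_K3] + k1 * Cass * Cass)
    Irel = p[_V_REL] * O * (CaSR - Cass)
    Ileak = p[_V_LEAK] * (CaSR - Cai)
    Iup = p[_VMAX_UP] / (1.0 + (p[_K_UP] / Cai) ** 2)
    Ixfer = p[_V_XFER] * (Cass - Cai)

    # --- concentration derivatives (instantaneous-buffer formulation) ---
    Cm = p[_CM]; Vc = p[_V_C]; Vsr = p[_V_SR]; Vss = p[_V_SS]
    buf_c = 1.0 / (1.0 + p[_BUFC] * p[_KBUFC] / ((Cai + p[_KBUFC]) ** 2))
    buf_sr = 1.0 / (1.0 + p[_BUFSR] * p[_KBUFSR] / ((CaSR + p[_KBUFSR]) ** 2))
    buf_ss = 1.0 / (1.0 + p[_BUFSS] * p[_KBUFSS] / ((Cass + p[_KBUFSS]) ** 2))

    dCai = buf_c * ((Ileak - Iup) * Vsr / Vc + Ixfer -
                    (IbCa + IpCa - 2.0 * INaCa) * Cm / (2.0 * Vc * F))
    dCaSR = buf_sr * (Iup - Irel - Ileak)
    dCass = buf_ss * (-ICaL * Cm / (2.0 * Vss * F) +
                      Irel * Vsr / Vss - Ixfer * Vc / Vss)
    dNai = -(INa + IbNa + 3.0 * INaK + 3.0 * INaCa) * Cm / (Vc * F)
    dKi = -(IK1 + Ito + IKr + IKs + IpK + i_stim - 2.0 * INaK) * Cm / (Vc * F)

    out[0] = -(Iion + i_stim)
    out[1] = (xr1_inf - Xr1) / tau_xr1
    out[2] = (xr2_inf - Xr2) / tau_xr2
    out[3] = (xs_inf - Xs) / tau_xs
    out[4] = (m_inf - m) / tau_m
    out[5] = (h_inf - h) / tau_h
    out[6] = (j_inf - j) / tau_j
    out[7] = (d_inf - d) / tau_d
    out[8] = (f_inf - f) / tau_f
    out[9] = (f2_inf - f2) / tau_f2
    out[10] = (fcass_inf - fCass) / tau_fcass
    out[11] = (s_inf - s) / tau_s
    out[12] = (r_inf - r) / tau_r
    out[13] = rbar_inf / tau_rbar - Rbar / tau_rbar
    out[14] = dCai
    out[15] = dCaSR
    out[16] = dCass
    out[17] = dNai
    out[18] = dKi

    out[INF_OFF + 0] = xr1_inf
    out[INF_OFF + 1] = xr2_inf
    out[INF_OFF + 2] = xs_inf
    out[INF_OFF + 3] = m_inf
    out[INF_OFF + 4] = h_inf
    out[INF_OFF + 5] = j_inf
    out[INF_OFF + 6] = d_inf
    out[INF_OFF + 7] = f_inf
    out[INF_OFF + 8] = f2_inf
    out[INF_OFF + 9] = fcass_inf
    out[INF_OFF + 10] = s_inf
    out[INF_OFF + 11] = r_inf
    out[INF_OFF + 12] = rbar_inf

    out[TAU_OFF + 0] = tau_xr1
    out[TAU_OFF + 1] = tau_xr2
    out[TAU_OFF + 2] = tau_xs
    out[TAU_OFF + 3] = tau_m
    out[TAU_OFF + 4] = tau_h
    out[TAU_OFF + 5] = tau_j
    out[TAU_OFF + 6] = tau_d
    out[TAU_OFF + 7] = tau_f
    out[TAU_OFF + 8] = tau_f2
    out[TAU_OFF + 9] = tau_fcass
    out[TAU_OFF + 10] = tau_s
    out[TAU_OFF + 11] = tau_r
    out[TAU_OFF + 12] = tau_rbar

    out[CUR_OFF + 0] = ICaL
    out[CUR_OFF + 1] = IKr
    out[CUR_OFF + 2] = IKs
    out[CUR_OFF + 3] = INa
    out[CUR_OFF + 4] = IK1
    out[CUR_OFF + 5] = Ito
    out[CUR_OFF + 6] = INaCa
    out[CUR_OFF + 7] = INaK
    out[CUR_OFF + 8] = IpCa
    out[CUR_OFF + 9] = IpK
    out[CUR_OFF + 10] = IbNa
    out[CUR_OFF + 11] = IbCa


@njit(cache=True)
def run_schedule(y, p, cl, enabled, amp, dur, dt,
                 clamp_flags, coefs, ncoef, vlo, vhi, blank,
                 rec_stride, rec_t, rec_v, rec_i, rec_cai):
    """Integrate a full pacing schedule beat by beat.

    Beat ``b`` occupies the window [T_b, T_b + cl[b]) and, if enabled,
    receives a square pulse of magnitude ``amp`` (depolarizing) for ``dur``
    ms at its start.  Per beat the kernel records capture, upstroke time
    (quadratically refined argmax of dV/dt) and APD_-60mV (interpolated
    downward crossing).  APs that have not repolarized when the next
    stimulus arrives stay open and close at the true crossing; an AP still
    open at the end of the run keeps APD = nan.

    If ``rec_stride > 0`` every ``rec_stride``-th step is sampled into the
    ``rec_*`` buffers (t, V, the three plateau currents, cytosolic Ca).
    Returns per-beat arrays plus the number of recorded samples.
    """
    nb = cl.size
    captured = np.zeros(nb, dtype=np.int64)
    t_up = np.full(nb, np.nan)
    apd = np.full(nb, np.nan)
    dvdt_max = np.zeros(nb)
    t_stim = np.zeros(nb)

    out = np.empty(EVAL_LEN)
    clamp_now = np.zeros(3, dtype=np.int64)

    t = 0.0
    nrec = 0
    last_up = -1.0e9          # most recent upstroke (blanking reference)
    open_beat = -1            # beat index of the AP awaiting -60 mV crossing
    open_t_up = 0.0

    for b in range(nb):
        t_stim[b] = t
        nsteps = int(round(cl[b] / dt))
        stim_steps = int(round(dur / dt))
        win_steps = int(round(20.0 / dt))
        is_on = enabled[b] == 1

        # capture-window tracking
        best_dvdt = -1.0e9
        best_t = 0.0
        prev_dvdt = 0.0
        best_prev = 0.0
        best_next = np.nan
        want_next = False
        vmax_win = -1.0e9
        seen_upstroke = False
        v_onset = y[0]

        for k in range(nsteps):
            tk = t + k * dt
            i_stim = -amp if (is_on and k < stim_steps) else 0.0

            # clamp applies outside the post-upstroke blanking window;
            # during an imminent upstroke (stimulated, not yet risen) the
            # native gating is also kept so the blank covers the whole
            # rising phase
            for ci in range(3):
                if clamp_flags[ci] == 1:
                    active = (tk - last_up) > blank[ci]
                    if is_on and k < win_steps and not seen_upstroke:
                        active = False
                    clamp_now[ci] = 1 if active else 0
                else:
                    clamp_now[ci] = 0

            tp06_eval(y, p, i_stim, clamp_now, coefs, ncoef, vlo, vhi, out)

            if rec_stride > 0:
                if (k % rec_stride) == 0:
                    rec_t[nrec] = tk
                    rec_v[nrec] = y[0]
                    rec_i[0, nrec] = out[CUR_OFF + 0]
                    rec_i[1, nrec] = out[CUR_OFF + 1]
                    rec_i[2, nrec] = out[CUR_OFF + 2]
                    rec_cai[nrec] = y[14]
                    nrec += 1

            v_old = y[0]
            dvdt = out[0]

            # upstroke bookkeeping inside the 20 ms capture window
            if is_on and k < win_steps:
                if want_next:
                    best_next = dvdt
                    want_next = False
                if dvdt > best_dvdt:
                    best_prev = prev_dvdt
                    best_dvdt = dvdt
                    best_t = tk
                    want_next = True
                if v_old > vmax_win:
                    vmax_win = v_old
                if (not seen_upstroke) and v_old > -20.0 and dvdt > 0.0:
                    seen_upstroke = True
                    last_up = tk

            # advance: Euler for V and concentrations
            y[0] = y[0] + dt * out[0]
            y[14] = y[14] + dt * out[14]
            y[15] = y[15] + dt * out[15]
            y[16] = y[16] + dt * out[16]
            y[17] = y[17] + dt * out[17]
            y[18] = y[18] + dt * out[18]
            # Rush-Larsen for relaxation variables
            for g in range(13):
                inf = out[INF_OFF + g]
                tau = out[TAU_OFF + g]
                y[1 + g] = inf + (y[1 + g] - inf) * math.exp(-dt / tau)

            # close the capture window: classify and time the upstroke.
            # A beat captures iff the membrane was repolarized (< -40 mV)
            # when its stimulus arrived and V then exceeded 0 mV; a
            # stimulus landing on an unrepolarized membrane is a merged/
            # blocked beat, not a new AP.
            if is_on and k == win_steps - 1:
                if vmax_win > 0.0 and v_onset < -40.0:
                    captured[b] = 1
                    t_ref = best_t
                    if not np.isnan(best_next):
                        den = best_prev - 2.0 * best_dvdt + best_next
                        if den < -1e-12:
                            delta = 0.5 * dt * (best_prev - best_next) / den
                            if -dt < delta < dt:
                                t_ref = best_t + delta
                    t_up[b] = t_ref
                    dvdt_max[b] = best_dvdt
                    open_beat = b
                    open_t_up = t_ref

            # APD: downward crossing of -60 mV closes the open AP
            if open_beat >= 0 and v_old > -60.0 and y[0] <= -60.0:
                frac = (v_old + 60.0) / (v_old - y[0])
                t_cross = tk + frac * dt
                apd[open_beat] = t_cross - open_t_up
                open_beat = -1

            prev_dvdt = dvdt

        t += nsteps * dt

    return captured, t_up, apd, dvdt_max, t_stim, nrec
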