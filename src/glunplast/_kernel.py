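"""Numba-compiled integration core shared by every simulation entry point.

All model state lives in one flat float64 vector so the whole
neuron + receptor + plasticity system can be advanced in a single jitted
loop at dt = 0.025 ms.  The scalar helpers (`mg_gate_scalar`, `hill_scalar`,
low-pass updates, the two-compartment sub-step) are the single source of the
model math; the public modules wrap them with validation and docstrings.
"""

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------- state layout
IVS, IVD = 0, 1
IH, IN = 2, 3
ISS, ICS, IQS, ICAS = 4, 5, 6, 7
ISD, ICD, IQD, ICAD = 8, 9, 10, 11
IRON_A, IROFF_A, IRON_B, IROFF_B, IPULSE = 12, 13, 14, 15, 16
IAX, IAY = 17, 18
IW = 19
IGBP, IGBM = 20, 21
ITHP, ITHM = 22, 23
IVBP, IVBM = 24, 25
IXB = 26
NSTATE = 27

# ------------------------------------------------------------- neuron params
NP_CM, NP_GC, NP_P = 0, 1, 2
NP_GLS, NP_GLD, NP_EL = 3, 4, 5
NP_GNA, NP_ENA, NP_GKDR, NP_EK = 6, 7, 8, 9
NP_GCAS, NP_ECA, NP_GKCS, NP_GKAHPS = 10, 11, 12, 13
NP_GCAD, NP_GKCD, NP_GKAHPD = 14, 15, 16
N_NPAR = 17

# ------------------------------------------------------------ synapse params
SP_A2A, SP_B2A, SP_G2A = 0, 1, 2
SP_A2B, SP_B2B, SP_G2B = 3, 4, 5
SP_MG, SP_PULSE, SP_BLOCK = 6, 7, 8
SP_AGMAX, SP_ATAUR, SP_ATAUD, SP_AEREV = 9, 10, 11, 12
SP_ENMDA, SP_KSYN, SP_MODE = 13, 14, 15
N_SPAR = 16

# --------------------------------------------------------- plasticity params
PP_AP, PP_AM = 0, 1
PP_KAP, PP_KAM, PP_NP, PP_NM = 2, 3, 4, 5
PP_TGP, PP_TGM = 6, 7
PP_TTHP, PP_TTHM, PP_BTHP, PP_BTHM = 8, 9, 10, 11
PP_THVP, PP_THVM, PP_TVP, PP_TVM = 12, 13, 14, 15
PP_TX, PP_WMIN, PP_WMAX = 16, 17, 18
PP_K2BP, PP_K2BM, PP_GSCALE, PP_XSC = 19, 20, 21, 22
N_PPAR = 23

# ------------------------------------------------------------ record columns
REC_T, REC_VS, REC_VD = 0, 1, 2
REC_G2A, REC_G2B, REC_GAMPA = 3, 4, 5
REC_W, REC_GBP, REC_GBM = 6, 7, 8
REC_PHIP, REC_PHIM, REC_THP, REC_THM = 9, 10, 11, 12
REC_VBP, REC_VBM, REC_XB = 13, 14, 15
N_REC = 16


@njit(cache=True)
def mg_gate_scalar(v, mg):
    """Jahr-Stevens magnesium unblock fraction at membrane potential v (mV)."""
    return 1.0 / (1.0 + math.exp(-0.062 * v) * mg / 3.57)


@njit(cache=True)
def hill_scalar(gbar, ka, n):
    """Hill occupancy 1/(1+(ka/gbar)^n); zero for non-positive input."""
    if gbar <= 0.0:
        return 0.0
    return 1.0 / (1.0 + (ka / gbar) ** n)


@njit(cache=True)
def lowpass_scalar(x, target, dt, tau):
    """Exact one-step update of tau dx/dt = target - x (exponential Euler)."""
    return target + (x - target) * math.exp(-dt / tau)


@njit(cache=True)
def _vtrap(x, y):
    # x / (exp(x/y) - 1) with the removable singularity patched
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / (2.0 * y))
    return x / (math.exp(x / y) - 1.0)


@njit(cache=True)
def _gate_step(x, a, b, dt):
    # exponential-Euler update for dx/dt = a(1-x) - b x
    tot = a + b
    if tot <= 0.0:
        return x
    xinf = a / tot
    return xinf + (x - xinf) * math.exp(-dt * tot)


@njit(cache=True)
def neuron_step(y, npar, dt, i_soma, i_syn_dend):
    """Advance the two-compartment neuron by one step.

    i_soma: injected somatic current (uA/cm^2, positive depolarizing);
    i_syn_dend: synaptic current into the dendrite (uA/cm^2, positive
    outward, i.e. already g*(V - E)).  Returns 0 on success, 1 on blow-up.
    """
    vs = y[IVS]
    vd = y[IVD]
    cm = npar[NP_CM]
    gc = npar[NP_GC]
    p = npar[NP_P]

    # --- somatic gates (m instantaneous)
    a_m = 0.32 * _vtrap(-46.9 - vs, 4.0)
    b_m = 0.28 * _vtrap(vs + 19.9, 5.0)
    minf = a_m / (a_m + b_m)
    a_h = 0.128 * math.exp((-43.0 - vs) / 18.0)
    b_h = 4.0 / (1.0 + math.exp((-20.0 - vs) / 5.0))
    a_n = 0.016 * _vtrap(-24.9 - vs, 5.0)
    b_n = 0.25 * math.exp(-1.0 - 0.025 * vs)
    a_ss = 1.6 / (1.0 + math.exp(-0.072 * (vs - 5.0)))
    b_ss = 0.02 * _vtrap(vs + 8.9, 5.0)
    if vs <= -10.0:
        a_cs = 0.0527 * math.exp((vs + 50.0) / 11.0 - (vs + 53.5) / 27.0)
        b_cs = 2.0 * math.exp((-53.5 - vs) / 27.0) - a_cs
    else:
        a_cs = 2.0 * math.exp((-53.5 - vs) / 27.0)
        b_cs = 0.0
    a_qs = min(0.00002 * y[ICAS], 0.01)

    # --- dendritic gates
    a_sd = 1.6 / (1.0 + math.exp(-0.072 * (vd - 5.0)))
    b_sd = 0.02 * _vtrap(vd + 8.9, 5.0)
    if vd <= -10.0:
        a_cd = 0.0527 * math.exp((vd + 50.0) / 11.0 - (vd + 53.5) / 27.0)
        b_cd = 2.0 * math.exp((-53.5 - vd) / 27.0) - a_cd
    else:
        a_cd = 2.0 * math.exp((-53.5 - vd) / 27.0)
        b_cd = 0.0
    a_qd = min(0.00002 * y[ICAD], 0.01)

    chi_s = min(y[ICAS] / 250.0, 1.0)
    chi_d = min(y[ICAD] / 250.0, 1.0)

    # --- currents (positive outward)
    i_na = npar[NP_GNA] * minf * minf * y[IH] * (vs - npar[NP_ENA])
    i_kdr = npar[NP_GKDR] * y[IN] * (vs - npar[NP_EK])
    i_ca_s = npar[NP_GCAS] * y[ISS] * y[ISS] * (vs - npar[NP_ECA])
    i_kc_s = npar[NP_GKCS] * y[ICS] * chi_s * (vs - npar[NP_EK])
    i_ahp_s = npar[NP_GKAHPS] * y[IQS] * (vs - npar[NP_EK])
    i_leak_s = npar[NP_GLS] * (vs - npar[NP_EL])

    i_ca_d = npar[NP_GCAD] * y[ISD] * y[ISD] * (vd - npar[NP_ECA])
    i_kc_d = npar[NP_GKCD] * y[ICD] * chi_d * (vd - npar[NP_EK])
    i_ahp_d = npar[NP_GKAHPD] * y[IQD] * (vd - npar[NP_EK])
    i_leak_d = npar[NP_GLD] * (vd - npar[NP_EL])

    dvs = (-i_na - i_kdr - i_ca_s - i_kc_s - i_ahp_s - i_leak_s
           + gc / p * (vd - vs) + i_soma / p) / cm
    dvd = (-i_ca_d - i_kc_d - i_ahp_d - i_leak_d
           + gc / (1.0 - p) * (vs - vd) - i_syn_dend / (1.0 - p)) / cm

    y[IVS] = vs + dt * dvs
    y[IVD] = vd + dt * dvd

    y[IH] = _gate_step(y[IH], a_h, b_h, dt)
    y[IN] = _gate_step(y[IN], a_n, b_n, dt)
    y[ISS] = _gate_step(y[ISS], a_ss, b_ss, dt)
    y[ICS] = _gate_step(y[ICS], a_cs, b_cs, dt)
    y[IQS] = _gate_step(y[IQS], a_qs, 0.001, dt)
    y[ISD] = _gate_step(y[ISD], a_sd, b_sd, dt)
    y[ICD] = _gate_step(y[ICD], a_cd, b_cd, dt)
    y[IQD] = _gate_step(y[IQD], a_qd, 0.001, dt)

    y[ICAS] = y[ICAS] + dt * (-0.13 * i_ca_s - 0.075 * y[ICAS])
    y[ICAD] = y[ICAD] + dt * (-0.13 * i_ca_d - 0.075 * y[ICAD])
    if y[ICAS] < 0.0:
        y[ICAS] = 0.0
    if y[ICAD] < 0.0:
        y[ICAD] = 0.0

    if abs(y[IVS]) > 200.0 or abs(y[IVD]) > 200.0:
        return 1
    return 0


@njit(cache=True)
def receptor_step(y, ron_i, roff_i, alpha, beta, dt, in_pulse, mode):
    """Advance one subunit's transmitter-binding state by dt.

    mode 0 (hand-off): during the pulse Ron relaxes toward Rinf; the open
    fraction is moved into Roff at pulse offset (done by the caller) and
    Roff decays with rate beta.  mode 1 (literal difference): Ron relaxes
    toward Rinf during the pulse and decays with beta outside it; Roff is a
    decaying shadow of pre-pulse activation loaded at pulse onset.
    """
    if in_pulse:
        rinf = alpha / (alpha + beta)
        tau = 1.0 / (alpha + beta)
        y[ron_i] = rinf + (y[ron_i] - rinf) * math.exp(-dt / tau)
        y[roff_i] = y[roff_i] * math.exp(-beta * dt)
    else:
        y[roff_i] = y[roff_i] * math.exp(-beta * dt)
        if mode == 1:
            y[ron_i] = y[ron_i] * math.exp(-beta * dt)


@njit(cache=True)
def open_fraction_scalar(ron, roff, mode):
    if mode == 1:
        f = ron - roff
        return f if f > 0.0 else 0.0
    return ron + roff


@njit(cache=True)
def ampa_norm(tau_rise, tau_decay):
    """Peak value of exp(-t/tau_decay) - exp(-t/tau_rise) for normalization."""
    tp = (tau_rise * tau_decay / (tau_decay - tau_rise)) * math.log(
        tau_decay / tau_rise)
    return math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise)


@njit(cache=True)
def plasticity_step(y, ppar, g2a, g2b, vd, dt):
    """One update of the subunit-weighted voltage-based plasticity rule."""
    k2bp = ppar[PP_K2BP]
    k2bm = ppar[PP_K2BM]
    scale = ppar[PP_GSCALE]
    gp = (k2bp * g2b + (1.0 - k2bp) * g2a) * scale
    gm = (k2bm * g2b + (1.0 - k2bm) * g2a) * scale

    y[IGBP] = lowpass_scalar(y[IGBP], gp, dt, ppar[PP_TGP])
    y[IGBM] = lowpass_scalar(y[IGBM], gm, dt, ppar[PP_TGM])

    phi_p = hill_scalar(y[IGBP], ppar[PP_KAP], ppar[PP_NP]) - y[ITHP]
    if phi_p < 0.0:
        phi_p = 0.0
    phi_m = hill_scalar(y[IGBM], ppar[PP_KAM], ppar[PP_NM]) - y[ITHM]
    if phi_m < 0.0:
        phi_m = 0.0

    # cross-coupled moving thresholds: LTP activity raises the LTD threshold
    y[ITHM] = lowpass_scalar(y[ITHM], ppar[PP_BTHM] * phi_p, dt, ppar[PP_TTHM])
    y[ITHP] = lowpass_scalar(y[ITHP], ppar[PP_BTHP] * phi_m, dt, ppar[PP_TTHP])

    vp = vd - ppar[PP_THVP]
    if vp < 0.0:
        vp = 0.0
    vm = vd - ppar[PP_THVM]
    if vm < 0.0:
        vm = 0.0
    y[IVBP] = lowpass_scalar(y[IVBP], vp, dt, ppar[PP_TVP])
    y[IVBM] = lowpass_scalar(y[IVBM], vm, dt, ppar[PP_TVM])

    y[IXB] = y[IXB] * math.exp(-dt / ppar[PP_TX])

    w = y[IW]
    dw = (ppar[PP_AP] * phi_p * y[IVBP] * (ppar[PP_WMAX] - w)
          - ppar[PP_AM] * phi_m * y[IVBM] * y[IXB] * (w - ppar[PP_WMIN]))
    w = w + dt * dw
    if w < ppar[PP_WMIN]:
        w = ppar[PP_WMIN]
    elif w > ppar[PP_WMAX]:
        w = ppar[PP_WMAX]
    y[IW] = w
    return phi_p, phi_m


@njit(cache=True)
def simulate(n_steps, dt, y, npar, spar, ppar,
             pre_steps, pulse_on, pulse_dur, pulse_amp,
             rec_stride, plastic):
    """Advance the full system n_steps; returns (status, rec, spikes, nspk).

    pre_steps: sorted step indices of presynaptic spikes.
    pulse_on/pulse_dur/pulse_amp: somatic current pulse windows (steps, steps,
    uA/cm^2), sorted and non-overlapping.
    rec_stride <= 0 disables recording.  Spike times are upward -20 mV
    crossings of the somatic potential with a 2 ms refractory period.
    """
    mode = int(spar[SP_MODE])
    a2a, b2a = spar[SP_A2A], spar[SP_B2A]
    a2b, b2b = spar[SP_A2B], spar[SP_B2B]
    ghat2a = spar[SP_G2A]
    ghat2b = spar[SP_G2B] * spar[SP_BLOCK]
    mg = spar[SP_MG]
    pulse_ms = spar[SP_PULSE]
    agmax = spar[SP_AGMAX]
    anorm = ampa_norm(spar[SP_ATAUR], spar[SP_ATAUD])
    dec_r = math.exp(-dt / spar[SP_ATAUR])
    dec_d = math.exp(-dt / spar[SP_ATAUD])
    ksyn = spar[SP_KSYN]
    inv_tx = ppar[PP_XSC] / ppar[PP_TX]

    n_rec = 0
    if rec_stride > 0:
        n_rec = n_steps // rec_stride + 1
    rec = np.zeros((n_rec, N_REC))
    spikes = np.zeros(100000)
    nspk = 0
    last_spike = -1.0e9

    ipre = 0
    ipulse = 0
    rec_row = 0
    status = 0
    phi_p = 0.0
    phi_m = 0.0

    for step in range(n_steps):
        t = step * dt

        # ---- presynaptic events
        while ipre < pre_steps.size and pre_steps[ipre] == step:
            if mode == 1:
                y[IROFF_A] += y[IRON_A]
                y[IROFF_B] += y[IRON_B]
                y[IRON_A] = 0.0
                y[IRON_B] = 0.0
            else:
                y[IRON_A] += y[IROFF_A]
                y[IRON_B] += y[IROFF_B]
                y[IROFF_A] = 0.0
                y[IROFF_B] = 0.0
            y[IPULSE] = pulse_ms
            y[IXB] += inv_tx
            y[IAX] += y[IW]
            y[IAY] += y[IW]
            ipre += 1

        # ---- somatic command current
        i_soma = 0.0
        while (ipulse < pulse_on.size
               and step >= pulse_on[ipulse] + pulse_dur[ipulse]):
            ipulse += 1
        if (ipulse < pulse_on.size and step >= pulse_on[ipulse]):
            i_soma = pulse_amp[ipulse]

        # ---- receptor kinetics
        in_pulse = y[IPULSE] > 0.0
        receptor_step(y, IRON_A, IROFF_A, a2a, b2a, dt, in_pulse, mode)
        receptor_step(y, IRON_B, IROFF_B, a2b, b2b, dt, in_pulse, mode)
        if in_pulse:
            y[IPULSE] -= dt
            if y[IPULSE] <= 0.0 and mode == 0:
                y[IROFF_A] += y[IRON_A]
                y[IROFF_B] += y[IRON_B]
                y[IRON_A] = 0.0
                y[IRON_B] = 0.0

        # ---- conductances at the (pre-update) dendritic potential
        vd = y[IVD]
        fmg = mg_gate_scalar(vd, mg)
        g2a = fmg * open_fraction_scalar(y[IRON_A], y[IROFF_A], mode) * ghat2a
        g2b = fmg * open_fraction_scalar(y[IRON_B], y[IROFF_B], mode) * ghat2b

        # ---- AMPA conductance (weight folded in at event time)
        y[IAX] *= dec_r
        y[IAY] *= dec_d
        g_ampa = agmax * (y[IAY] - y[IAX]) / anorm
        if g_ampa < 0.0:
            g_ampa = 0.0

        i_syn = ksyn * (g_ampa * (vd - spar[SP_AEREV])
                        + (g2a + g2b) * (vd - spar[SP_ENMDA]))

        vs_old = y[IVS]
        status = neuron_step(y, npar, dt, i_soma, i_syn)
        if status != 0:
            break

        if plastic:
            phi_p, phi_m = plasticity_step(y, ppar, g2a, g2b, vd, dt)

        # ---- somatic spike detection
        if y[IVS] >= -20.0 and vs_old < -20.0 and (t - last_spike) > 2.0:
            if nspk < spikes.size:
                spikes[nspk] = t + dt
            nspk += 1
            last_spike = t

        if rec_stride > 0 and step % rec_stride == 0:
            rec[rec_row, REC_T] = t
            rec[rec_row, REC_VS] = y[IVS]
            rec[rec_row, REC_VD] = y[IVD]
            rec[rec_row, REC_G2A] = g2a
            rec[rec_row, REC_G2B] = g2b
            rec[rec_row, REC_GAMPA] = g_ampa
            rec[rec_row, REC_W] = y[IW]
            rec[rec_row, REC_GBP] = y[IGBP]
            rec[rec_row, REC_GBM] = y[IGBM]
            rec[rec_row, REC_PHIP] = phi_p
            rec[rec_row, REC_PHIM] = phi_m
            rec[rec_row, REC_THP] = y[ITHP]
            rec[rec_row, REC_THM] = y[ITHM]
            rec[rec_row, REC_VBP] = y[IVBP]
            rec[rec_row, REC_VBM] = y[IVBM]
            rec[rec_row, REC_XB] = y[IXB]
            rec_row += 1

    return status, rec[:rec_row], spikes[:min(nspk, spikes.size)], nspk
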