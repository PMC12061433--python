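"""Compiled time-stepping kernel for the thalamocortical network.

One numba-jitted loop advances every state variable of the network
(90 L5_PT soma/apical pairs, 90 basket cells, 10 thalamic cells) with the
hybrid scheme: conductances decay exactly (analytic exponential) between
instantaneous spike jumps, membrane equations advance by forward Euler,
and threshold crossings are handled by clamp-and-reset at step boundaries.
Spikes emitted at step k reach conductances at step k+1 (no delays are
modelled otherwise).  A single seeded RNG stream with a fixed draw order
makes runs bit-reproducible for a given (config, seed).
"""

import numpy as np
from numba import njit

# error codes returned by the kernel
OK = 0
BLOWUP = 1
OVERFLOW = 2


@njit(cache=True)
def run_kernel(seed, steps, dt, record_every,
               # Izhikevich params per population: [C,k,vr,vt,a,b,c,d,vpeak]
               pE, pI, pT,
               c_RS, d_RS, c_IB, d_IB,
               # apical: [C,l,g,m,vr,a,b,f_half,f_slope,plateau_thr]
               pA,
               bap_delay_steps, bap_dur_steps,
               # synapse constants
               tau_ampa, tau_gaba, tau_nmda, tau_coup, tau_adapt,
               dg_adapt, E_exc, E_inh, E_adapt, nmda_clip,
               # weights
               W_EE_A, W_EE_N, W_EI, W_IE, w_eth, w_thd_a, w_thd_n, block,
               ee_to_apical,
               # per-cell Poisson means per step (spikes/step), unit weight
               lam_bgE, lam_bgI, lam_bgT, lam_ap, lamL, lamR, w_ext,
               shared_eye_trains, lam_eyeL, lam_eyeR, hL, hR,
               noise_free,
               # current injections
               pulse_I, pulse_on, pulse_off,
               kick_I, kick_on, kick_off,
               pert_ap, pert_th,
               # initial somatic voltage offsets (asymmetric-init probe)
               init_vs_offset,
               capE, capI, capT):
    nE = lam_bgE.shape[0]
    nI = lam_bgI.shape[0]
    nT = lam_bgT.shape[0]

    np.random.seed(seed)

    # --- state -----------------------------------------------------------
    v_s = np.full(nE, pE[2]) + init_vs_offset
    u_s = np.zeros(nE)
    v_d = np.full(nE, pA[4])
    u_d = np.zeros(nE)
    v_i = np.full(nI, pI[2])
    u_i = np.zeros(nI)
    v_t = np.full(nT, pT[2])
    u_t = np.zeros(nT)
    regime = np.zeros(nE, dtype=np.uint8)       # 0 = RS, 1 = IB
    prev_above = np.zeros(nE, dtype=np.uint8)
    g_coup = np.zeros(nE)
    g_adapt = np.zeros(nE)

    g_ampa_E = np.zeros(nE)
    g_nmda_E = np.zeros(nE)
    g_gaba_E = np.zeros(nE)
    g_ampa_I = np.zeros(nI)
    g_nmda_I = np.zeros(nI)
    g_ampa_T = np.zeros(nT)
    g_ampa_D = np.zeros(nE)
    g_nmda_D = np.zeros(nE)

    spkE_prev = np.zeros(nE, dtype=np.uint8)
    spkI_prev = np.zeros(nI, dtype=np.uint8)
    spkT_prev = np.zeros(nT, dtype=np.uint8)

    L = bap_delay_steps + bap_dur_steps + 2
    bap_delta = np.zeros((L, nE), dtype=np.int32)
    bap_cnt = np.zeros(nE, dtype=np.int32)

    dec_a = np.exp(-dt / tau_ampa)
    dec_g = np.exp(-dt / tau_gaba)
    dec_n = np.exp(-dt / tau_nmda)
    dec_c = np.exp(-dt / tau_coup)
    dec_ad = np.exp(-dt / tau_adapt)

    # --- outputs ---------------------------------------------------------
    spkE = np.empty((capE, 2), dtype=np.int64)
    spkI = np.empty((capI, 2), dtype=np.int64)
    spkT = np.empty((capT, 2), dtype=np.int64)
    nspkE = 0
    nspkI = 0
    nspkT = 0

    nrec = (steps + record_every - 1) // record_every
    rec_regime = np.zeros((nrec, nE), dtype=np.uint8)
    rec_apI = np.zeros((nrec, nE), dtype=np.float32)
    rec_coup = np.zeros((nrec, nE), dtype=np.float32)

    sum_exc = 0.0     # summed excitatory synaptic current onto L5 somas
    sum_inh = 0.0     # summed inhibitory synaptic current onto L5 somas
    sum_gexc = 0.0    # summed excitatory conductance onto L5 somas
    sum_ginh = 0.0    # summed inhibitory conductance onto L5 somas
    min_g = 0.0
    max_nmda = 0.0
    min_coup = 0.0
    max_coup = 0.0

    extE = np.zeros(nE)
    extD = np.zeros(nE)
    extI = np.zeros(nI)
    extT = np.zeros(nT)
    I_E = np.zeros(nE)
    I_D = np.zeros(nE)

    err = OK
    err_cell = -1
    err_step = -1

    for step in range(steps):
        # (1) external drive ------------------------------------------------
        if noise_free:
            for i in range(nE):
                extE[i] = lam_bgE[i] + lamL[i] + lamR[i]
                extD[i] = lam_ap[i]
            for i in range(nI):
                extI[i] = lam_bgI[i]
            for i in range(nT):
                extT[i] = lam_bgT[i]
        else:
            # one Poisson process per eye: every cell on a side shares the
            # same train, scaled by its Gaussian footprint weight
            nL = 0
            nR = 0
            if shared_eye_trains:
                if lam_eyeL > 0.0:
                    nL = np.random.poisson(lam_eyeL)
                if lam_eyeR > 0.0:
                    nR = np.random.poisson(lam_eyeR)
            for i in range(nE):
                cnt = 0.0
                if lam_bgE[i] > 0.0:
                    cnt += np.random.poisson(lam_bgE[i])
                if shared_eye_trains:
                    cnt += hL[i] * nL + hR[i] * nR
                else:
                    if lamL[i] > 0.0:
                        cnt += np.random.poisson(lamL[i])
                    if lamR[i] > 0.0:
                        cnt += np.random.poisson(lamR[i])
                extE[i] = cnt
                if lam_ap[i] > 0.0:
                    extD[i] = np.random.poisson(lam_ap[i])
                else:
                    extD[i] = 0.0
            for i in range(nI):
                if lam_bgI[i] > 0.0:
                    extI[i] = np.random.poisson(lam_bgI[i])
                else:
                    extI[i] = 0.0
            for i in range(nT):
                if lam_bgT[i] > 0.0:
                    extT[i] = np.random.poisson(lam_bgT[i])
                else:
                    extT[i] = 0.0

        # (2) conductances: exact decay + jumps from last step's spikes -----
        for i in range(nE):
            g_ampa_E[i] = g_ampa_E[i] * dec_a + w_ext * extE[i]
            g_nmda_E[i] = g_nmda_E[i] * dec_n
            g_gaba_E[i] = g_gaba_E[i] * dec_g
            g_ampa_D[i] = g_ampa_D[i] * dec_a + w_ext * extD[i]
            g_nmda_D[i] = g_nmda_D[i] * dec_n
            g_coup[i] = g_coup[i] * dec_c
            g_adapt[i] = g_adapt[i] * dec_ad
        for i in range(nI):
            g_ampa_I[i] = g_ampa_I[i] * dec_a + w_ext * extI[i]
            g_nmda_I[i] = g_nmda_I[i] * dec_n
        for i in range(nT):
            g_ampa_T[i] = g_ampa_T[i] * dec_a + w_ext * extT[i]

        for j in range(nE):
            if spkE_prev[j] == 1:
                if ee_to_apical:
                    for i in range(nE):
                        g_ampa_D[i] += W_EE_A[i, j]
                        g_nmda_D[i] += W_EE_N[i, j]
                else:
                    for i in range(nE):
                        g_ampa_E[i] += W_EE_A[i, j]
                        g_nmda_E[i] += W_EE_N[i, j]
                for i in range(nI):
                    g_ampa_I[i] += W_EI[i, j]
                    g_nmda_I[i] += W_EI[i, j]
                g_ampa_T[j // block] += w_eth
        for j in range(nI):
            if spkI_prev[j] == 1:
                for i in range(nE):
                    g_gaba_E[i] += W_IE[i, j]
        for j in range(nT):
            if spkT_prev[j] == 1:
                for i in range(j * block, (j + 1) * block):
                    g_ampa_D[i] += w_thd_a
                    g_nmda_D[i] += w_thd_n
                    g_coup[i] = g_coup[i] + (1.0 - g_coup[i])

        for i in range(nE):
            if g_nmda_E[i] > nmda_clip:
                g_nmda_E[i] = nmda_clip
            if g_nmda_D[i] > nmda_clip:
                g_nmda_D[i] = nmda_clip
        for i in range(nI):
            if g_nmda_I[i] > nmda_clip:
                g_nmda_I[i] = nmda_clip

        # invariant trackers
        for i in range(nE):
            if g_coup[i] < min_coup:
                min_coup = g_coup[i]
            if g_coup[i] > max_coup:
                max_coup = g_coup[i]
            if g_nmda_E[i] > max_nmda:
                max_nmda = g_nmda_E[i]
            if g_nmda_D[i] > max_nmda:
                max_nmda = g_nmda_D[i]
            if g_ampa_E[i] < min_g:
                min_g = g_ampa_E[i]
            if g_gaba_E[i] < min_g:
                min_g = g_gaba_E[i]

        # (3) currents ------------------------------------------------------
        in_pulse = pulse_on <= step < pulse_off
        in_kick = kick_on <= step < kick_off
        idx = step % L
        for i in range(nE):
            x = ((v_s[i] + 80.0) / 60.0) ** 2
            gate_s = x / (1.0 + x)
            I_exc = (g_ampa_E[i] + g_nmda_E[i] * gate_s) * (E_exc - v_s[i])
            I_inh = g_gaba_E[i] * (E_inh - v_s[i])
            I_ad = g_adapt[i] * (E_adapt - v_s[i])
            sum_exc += I_exc
            sum_inh += I_inh
            sum_gexc += g_ampa_E[i] + g_nmda_E[i]
            sum_ginh += g_gaba_E[i]
            I = I_exc + I_inh + I_ad
            if in_pulse:
                I += pulse_I[i]
            if in_kick:
                I += kick_I[i]
            I_E[i] = I

            bap_cnt[i] += bap_delta[idx, i]
            bap_delta[idx, i] = 0
            x = ((v_d[i] + 80.0) / 60.0) ** 2
            gate_d = x / (1.0 + x)
            I_D[i] = ((g_ampa_D[i] + g_nmda_D[i] * gate_d) * (E_exc - v_d[i])
                      + pA[3] * bap_cnt[i] + pert_ap[i])

        # (4) apical compartments (forward Euler, no reset) -----------------
        for i in range(nE):
            v0 = v_d[i]
            f = 1.0 / (1.0 + np.exp(-(v0 - pA[7]) / pA[8]))
            dv = (-pA[1] * (v0 - pA[4]) + pA[2] * f + u_d[i] + I_D[i]) / pA[0]
            du = pA[5] * (pA[6] * (v0 - pA[4]) - u_d[i])
            v_d[i] = v0 + dt * dv
            u_d[i] = u_d[i] + dt * du
            above = v_d[i] > pA[9]
            if above:
                if prev_above[i] == 0:
                    # plateau onset: one Bernoulli(g_coupling) draw
                    # (deterministic threshold rule in noise-free mode)
                    if noise_free:
                        regime[i] = 1 if g_coup[i] >= 0.5 else 0
                    elif np.random.random() < g_coup[i]:
                        regime[i] = 1
                    else:
                        regime[i] = 0
                prev_above[i] = 1
            else:
                regime[i] = 0
                prev_above[i] = 0

        # (5) spiking compartments ------------------------------------------
        for i in range(nE):
            v0 = v_s[i]
            dv = (pE[1] * (v0 - pE[2]) * (v0 - pE[3]) - u_s[i] + I_E[i]) / pE[0]
            du = pE[4] * (pE[5] * (v0 - pE[2]) - u_s[i])
            v_s[i] = v0 + dt * dv
            u_s[i] = u_s[i] + dt * du
            spk = np.uint8(0)
            if v_s[i] >= pE[8]:
                spk = np.uint8(1)
                if nspkE >= capE:
                    err = OVERFLOW
                    err_cell = i
                    err_step = step
                    break
                spkE[nspkE, 0] = i
                spkE[nspkE, 1] = step
                nspkE += 1
                if regime[i] == 1:
                    v_s[i] = c_IB
                    u_s[i] += d_IB
                else:
                    v_s[i] = c_RS
                    u_s[i] += d_RS
                g_adapt[i] += dg_adapt
                # bAP gate: Bernoulli(g_coupling) per somatic spike
                # (deterministic threshold rule in noise-free mode)
                if (g_coup[i] >= 0.5) if noise_free else \
                        (np.random.random() < g_coup[i]):
                    bap_delta[(step + bap_delay_steps) % L, i] += 1
                    bap_delta[(step + bap_delay_steps + bap_dur_steps) % L, i] -= 1
            elif np.abs(v_s[i]) > 500.0 or not np.isfinite(v_s[i]):
                err = BLOWUP
                err_cell = i
                err_step = step
                break
            spkE_prev[i] = spk
        if err != OK:
            break

        for i in range(nI):
            x = ((v_i[i] + 80.0) / 60.0) ** 2
            gate = x / (1.0 + x)
            I = (g_ampa_I[i] + g_nmda_I[i] * gate) * (E_exc - v_i[i])
            v0 = v_i[i]
            dv = (pI[1] * (v0 - pI[2]) * (v0 - pI[3]) - u_i[i] + I) / pI[0]
            du = pI[4] * (pI[5] * (v0 - pI[2]) - u_i[i])
            v_i[i] = v0 + dt * dv
            u_i[i] = u_i[i] + dt * du
            spk = np.uint8(0)
            if v_i[i] >= pI[8]:
                spk = np.uint8(1)
                if nspkI >= capI:
                    err = OVERFLOW
                    err_cell = i
                    err_step = step
                    break
                spkI[nspkI, 0] = i
                spkI[nspkI, 1] = step
                nspkI += 1
                v_i[i] = pI[6]
                u_i[i] += pI[7]
            elif np.abs(v_i[i]) > 500.0 or not np.isfinite(v_i[i]):
                err = BLOWUP
                err_cell = i
                err_step = step
                break
            spkI_prev[i] = spk
        if err != OK:
            break

        for i in range(nT):
            I = g_ampa_T[i] * (E_exc - v_t[i]) + pert_th[i]
            v0 = v_t[i]
            dv = (pT[1] * (v0 - pT[2]) * (v0 - pT[3]) - u_t[i] + I) / pT[0]
            du = pT[4] * (pT[5] * (v0 - pT[2]) - u_t[i])
            v_t[i] = v0 + dt * dv
            u_t[i] = u_t[i] + dt * du
            spk = np.uint8(0)
            if v_t[i] >= pT[8]:
                spk = np.uint8(1)
                if nspkT >= capT:
                    err = OVERFLOW
                    err_cell = i
                    err_step = step
                    break
                spkT[nspkT, 0] = i
                spkT[nspkT, 1] = step
                nspkT += 1
                v_t[i] = pT[6]
                u_t[i] += pT[7]
            elif np.abs(v_t[i]) > 500.0 or not np.isfinite(v_t[i]):
                err = BLOWUP
                err_cell = i
                err_step = step
                break
            spkT_prev[i] = spk
        if err != OK:
            break

        # (6) record --------------------------------------------------------
        if step % record_every == 0:
            r = step // record_every
            for i in range(nE):
                rec_regime[r, i] = regime[i]
                rec_apI[r, i] = I_D[i]
                rec_coup[r, i] = g_coup[i]

    n_soma_steps = float(nE) * steps
    return (spkE[:nspkE], spkI[:nspkI], spkT[:nspkT],
            rec_regime, rec_apI, rec_coup,
            sum_exc / n_soma_steps, sum_inh / n_soma_steps,
            sum_gexc / n_soma_steps, sum_ginh / n_soma_steps,
            min_g, max_nmda, min_coup, max_coup,
            err, err_cell, err_step)
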