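"""Fixed-step integration kernel for single neurons and networks.

The electrophysiological state of ``n`` neurons is advanced with classical
RK4 at a fixed step (default 50 us, well inside the stability and accuracy
limits of the gating kinetics).  Within one outer window the oxygen seen by
each neuron -- and hence its maximal pump rate ``rho`` -- is held constant;
the window-averaged pump transport rate is returned so the caller can close
the oxygen balance.

State layout (rows of ``Y``, one column per neuron):

    0 V      membrane potential (mV)
    1 m      Na+ activation gate
    2 p      Na+ inactivation gate
    3 n      K+ activation gate
    4 Na_i   intracellular sodium (mM)
    5 K_o    extracellular potassium (mM)
    6 g      outgoing synaptic conductance (uS cm^-2, per presynaptic neuron)

Spikes are upward crossings of 0 mV detected on step boundaries; the
crossing time is linearly interpolated and the presynaptic conductance is
incremented by ``gbar`` at the end of the crossing step (a delay of at most
one step, << tau_syn).  The formulas duplicate :mod:`digitoids.neuron`;
unit tests assert term-by-term equality of the two derivative fields.
"""

import math

import numpy as np
from numba import njit

# indices into the scalar parameter vector
(P_CM, P_GNA, P_GK, P_GNAL, P_GKL, P_GCL, P_ECL, P_PHI, P_GAMMA, P_BETA,
 P_COEF, P_NAIREF, P_NAOREF, P_KIREF, P_KBATH, P_EPS, P_NAHALF, P_NASLOPE,
 P_KHALF) = range(19)

N_PARAMS = 19
N_STATE = 7
SPIKE_THRESHOLD = 0.0


def pack_params(mb, mp) -> np.ndarray:
    """Flatten MembraneParams + pump-current constants into the kernel vector."""
    pv = np.empty(N_PARAMS)
    pv[P_CM] = mb.C_m
    pv[P_GNA] = mb.G_Na
    pv[P_GK] = mb.G_K
    pv[P_GNAL] = mb.G_Na_leak
    pv[P_GKL] = mb.G_K_leak
    pv[P_GCL] = mb.G_Cl
    pv[P_ECL] = mb.E_Cl
    pv[P_PHI] = mb.phi
    pv[P_GAMMA] = mb.gamma
    pv[P_BETA] = mb.beta
    pv[P_COEF] = mb.nernst_coef
    pv[P_NAIREF] = mb.Na_i_ref
    pv[P_NAOREF] = mb.Na_o_ref
    pv[P_KIREF] = mb.K_i_ref
    pv[P_KBATH] = mb.K_bath
    pv[P_EPS] = mb.eps_bath
    pv[P_NAHALF] = mp.na_half
    pv[P_NASLOPE] = mp.na_slope
    pv[P_KHALF] = mp.k_half
    return pv


@njit(cache=True)
def _deriv(Y, K, AT, Esyn, tau, rho, Iext, pv, clamp_ions, ipump_out):
    """Fill K with the state derivative at Y (per-second time base)."""
    n = Y.shape[1]
    g = Y[6]
    S0 = np.dot(AT, g)
    S1 = np.dot(AT, g * Esyn)
    for i in range(n):
        V = Y[0, i]
        m = Y[1, i]
        p = Y[2, i]
        ng = Y[3, i]
        Nai = Y[4, i]
        Ko = Y[5, i]
        # physical floors keep the Nernst logs defined if a pathological
        # parameter set drives a pool toward exhaustion
        if Nai < 1.0:
            Nai = 1.0
        if Ko < 0.1:
            Ko = 0.1
        Nao = pv[P_NAOREF] - pv[P_BETA] * (Nai - pv[P_NAIREF])
        if Nao < 1.0:
            Nao = 1.0
        Ki = pv[P_KIREF] + (pv[P_NAIREF] - Nai)
        if Ki < 1.0:
            Ki = 1.0
        E_Na = pv[P_COEF] * math.log(Nao / Nai)
        E_K = pv[P_COEF] * math.log(Ko / Ki)
        I_Na = (pv[P_GNA] * m * m * m * p + pv[P_GNAL]) * (V - E_Na)
        I_K = (pv[P_GK] * ng * ng * ng * ng + pv[P_GKL]) * (V - E_K)
        I_Cl = pv[P_GCL] * (V - pv[P_ECL])
        I_syn = S1[i] - S0[i] * V
        ip = rho[i] \
            / (1.0 + math.exp((pv[P_NAHALF] - Nai) / pv[P_NASLOPE])) \
            / (1.0 + math.exp(pv[P_KHALF] - Ko))
        ipump_out[i] = ip

        K[0, i] = 1e3 * (Iext[i] - I_Na - I_K - I_Cl + I_syn) / pv[P_CM]

        # gating rates (per ms), scaled to per-second
        x = V + 30.0
        if abs(x) < 1e-9:
            a_m = 1.0
        else:
            a_m = 0.1 * x / (1.0 - math.exp(-0.1 * x))
        b_m = 4.0 * math.exp(-(V + 55.0) / 18.0)
        a_p = 0.07 * math.exp(-(V + 44.0) / 20.0)
        b_p = 1.0 / (1.0 + math.exp(-0.1 * (V + 14.0)))
        x = V + 34.0
        if abs(x) < 1e-9:
            a_n = 0.1
        else:
            a_n = 0.01 * x / (1.0 - math.exp(-0.1 * x))
        b_n = 0.125 * math.exp(-(V + 44.0) / 80.0)
        K[1, i] = 1e3 * (a_m * (1.0 - m) - b_m * m)
        K[2, i] = 1e3 * pv[P_PHI] * (a_p * (1.0 - p) - b_p * p)
        K[3, i] = 1e3 * pv[P_PHI] * (a_n * (1.0 - ng) - b_n * ng)

        if clamp_ions:
            K[4, i] = 0.0
            K[5, i] = 0.0
        else:
            K[4, i] = -pv[P_GAMMA] * I_Na - 3.0 * ip
            K[5, i] = pv[P_GAMMA] * pv[P_BETA] * I_K - 2.0 * pv[P_BETA] * ip \
                + pv[P_EPS] * (pv[P_KBATH] - Ko)
        K[6, i] = -Y[6, i] / tau[i]


@njit(cache=True)
def integrate_window(Y, AT, Esyn, tau, gbar, rho, Iext, pv, clamp_ions,
                     dt, nsteps, t0, rec_stride, Vrec, Grec, record_g,
                     rec_offset, spike_t, spike_id):
    """Advance Y by nsteps RK4 steps of size dt, starting at absolute time t0.

    Records V every ``rec_stride`` steps into ``Vrec`` starting at column
    ``rec_offset``; appends detected spikes to the (spike_t, spike_id)
    buffers.  Returns (number of spikes appended, mean pump transport rate
    per neuron over the window).
    """
    n = Y.shape[1]
    K1 = np.empty((N_STATE, n))
    K2 = np.empty((N_STATE, n))
    K3 = np.empty((N_STATE, n))
    K4 = np.empty((N_STATE, n))
    Yt = np.empty((N_STATE, n))
    ip1 = np.empty(n)
    ipd = np.empty(n)
    Vprev = np.empty(n)
    ipump_sum = np.zeros(n)
    nspk = 0
    cap = spike_t.shape[0]
    rec = rec_offset
    for step in range(nsteps):
        for i in range(n):
            Vprev[i] = Y[0, i]
        _deriv(Y, K1, AT, Esyn, tau, rho, Iext, pv, clamp_ions, ip1)
        for r in range(N_STATE):
            for i in range(n):
                Yt[r, i] = Y[r, i] + 0.5 * dt * K1[r, i]
        _deriv(Yt, K2, AT, Esyn, tau, rho, Iext, pv, clamp_ions, ipd)
        for r in range(N_STATE):
            for i in range(n):
                Yt[r, i] = Y[r, i] + 0.5 * dt * K2[r, i]
        _deriv(Yt, K3, AT, Esyn, tau, rho, Iext, pv, clamp_ions, ipd)
        for r in range(N_STATE):
            for i in range(n):
                Yt[r, i] = Y[r, i] + dt * K3[r, i]
        _deriv(Yt, K4, AT, Esyn, tau, rho, Iext, pv, clamp_ions, ipd)
        for r in range(N_STATE):
            for i in range(n):
                Y[r, i] += dt / 6.0 * (K1[r, i] + 2.0 * K2[r, i]
                                       + 2.0 * K3[r, i] + K4[r, i])
        for i in range(n):
            ipump_sum[i] += ip1[i]
            # clip gates against integration round-off
            for r in range(1, 4):
                if Y[r, i] < 0.0:
                    Y[r, i] = 0.0
                elif Y[r, i] > 1.0:
                    Y[r, i] = 1.0
            if Vprev[i] < SPIKE_THRESHOLD and Y[0, i] >= SPIKE_THRESHOLD:
                if nspk < cap:
                    frac = (SPIKE_THRESHOLD - Vprev[i]) / (Y[0, i] - Vprev[i])
                    spike_t[nspk] = t0 + dt * (step + frac)
                    spike_id[nspk] = i
                    nspk += 1
                Y[6, i] += gbar
        if rec_stride > 0 and (step + 1) % rec_stride == 0:
            for i in range(n):
                Vrec[i, rec] = Y[0, i]
                if record_g:
                    Grec[i, rec] = Y[6, i]
            rec += 1
    for i in range(n):
        ipump_sum[i] /= nsteps
    return nspk, ipump_sum
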