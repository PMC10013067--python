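"""Compiled inner loops.

Fixed-step Euler-Maruyama integration of the compartmental Ca2+/IP3 system
and of the tripartite synapse, with per-step Markov jumps for the IP3R
gate chains and the vesicle-fusion sensor.  All stochastic transitions use
the exact exponential probability 1 - exp(-rate*dt) and allow at most one
jump per channel per step (valid because rate*dt << 1 at the default
steps; guarded where it could fail).

Everything here is an implementation detail: the public surface lives in
`astro_model` and `synapse_model`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# astro parameter packing
# ---------------------------------------------------------------------------

(A_N, A_C0, A_C1, A_V1, A_V2, A_V3, A_V5, A_K1, A_K3N, A_K3P, A_K4, A_V4,
 A_VB, A_KG03, A_ALPHA, A_D1, A_D2, A_D3, A_D5, A_A2, A_TAU, A_IP3S,
 A_SIGH) = range(23)


def pack_astro(p) -> np.ndarray:
    out = np.empty(23)
    out[A_N] = float(p.N)
    out[A_C0] = p.c0
    out[A_C1] = p.c1
    out[A_V1] = p.v1
    out[A_V2] = p.v2
    out[A_V3] = p.v3
    out[A_V5] = p.v5
    out[A_K1] = p.k1
    out[A_K3N] = p.k3_node
    out[A_K3P] = p.k3_parent
    out[A_K4] = p.k4
    out[A_V4] = p.v4
    out[A_VB] = p.v_beta
    out[A_KG03] = p.k_g**0.3
    out[A_ALPHA] = p.alpha
    out[A_D1] = p.d1
    out[A_D2] = p.d2
    out[A_D3] = p.d3
    out[A_D5] = p.d5
    out[A_A2] = p.a2
    out[A_TAU] = p.tau_ip3_inv
    out[A_IP3S] = p.ip3_star
    out[A_SIGH] = p.sigma_h
    return out


# ---------------------------------------------------------------------------
# Markov gate chain helpers
# ---------------------------------------------------------------------------


@njit(cache=True)
def _moves(n, p_up, p_down):
    """Number of channels (out of n) jumping up / down this step.

    Each channel independently jumps up with probability p_up, down with
    p_down, else stays.  Sampled exactly: the mover count is binomial in
    p_up + p_down (inverse-CDF, fast path for the overwhelmingly common
    zero-mover case), then movers split binomially between directions.
    """
    if n == 0:
        return 0, 0
    pm = p_up + p_down
    if pm <= 0.0:
        return 0, 0
    pstay = 1.0 - pm
    if pstay <= 1e-12:  # pathological dt; everything moves
        m = n
    else:
        p0 = 1.0
        for _ in range(n):
            p0 *= pstay
        u = np.random.random()
        if u <= p0:
            return 0, 0
        m = 0
        pk = p0
        cum = p0
        ratio = pm / pstay
        while u > cum and m < n:
            m += 1
            pk = pk * (n - m + 1) / m * ratio
            cum += pk
    pu = p_up / pm
    up = 0
    for _ in range(m):
        if np.random.random() < pu:
            up += 1
    return up, m - up


@njit(cache=True)
def _gate_step(g, alpha, beta, dt):
    """One exact-probability step of the 4-state IP3R gate-count chain.

    ``g`` holds counts of channels with 0..3 open h-gates; a channel with
    i open gates opens another with rate (3-i)*alpha and closes one with
    rate i*beta.
    """
    ea = math.exp(-alpha * dt)
    eb = math.exp(-beta * dt)
    u0, _ = _moves(g[0], 1.0 - ea * ea * ea, 0.0)
    u1, d1 = _moves(g[1], 1.0 - ea * ea, 1.0 - eb)
    u2, d2 = _moves(g[2], 1.0 - ea, 1.0 - eb * eb)
    _, d3 = _moves(g[3], 0.0, 1.0 - eb * eb * eb)
    g[0] += -u0 + d1
    g[1] += u0 - u1 - d1 + d2
    g[2] += u1 - u2 - d2 + d3
    g[3] += u2 - d3


@njit(cache=True)
def gate_chain_kernel(counts, alpha, beta, dt, n_steps, burn, sample_every, seed):
    """Clamped-rate gate chain; returns sampled state-count matrix."""
    np.random.seed(seed)
    nsamp = (n_steps - burn) // sample_every
    out = np.zeros((nsamp, 4), np.int64)
    s = 0
    for step in range(n_steps):
        _gate_step(counts, alpha, beta, dt)
        if step >= burn and (step + 1 - burn) % sample_every == 0 and s < nsamp:
            out[s, 0] = counts[0]
            out[s, 1] = counts[1]
            out[s, 2] = counts[2]
            out[s, 3] = counts[3]
            s += 1
    return out


@njit(cache=True)
def sensor_chain_kernel(m_sensors, state0, pf, pb, n_steps, burn, sample_every, seed):
    """Clamped-Ca 7-state vesicle sensor chain over many independent sensors.

    Returns pooled occupancy counts of the 7 states over all samples.
    """
    np.random.seed(seed)
    states = np.full(m_sensors, state0, np.int64)
    occ = np.zeros(7, np.int64)
    for step in range(n_steps):
        for k in range(m_sensors):
            s = states[k]
            u = np.random.random()
            if u < pf[s]:
                states[k] = s + 1
            elif u < pf[s] + pb[s]:
                states[k] = s - 1
        if step >= burn and (step + 1 - burn) % sample_every == 0:
            for k in range(m_sensors):
                occ[states[k]] += 1
    return occ


# ---------------------------------------------------------------------------
# astro compartment-graph kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def astro_kernel(
    n_steps, dt, sample_every,
    kind, node_ord, indptr, indices, cca, cip, glut03,
    P, deterministic, seed,
    ca, ip3, gates, q, aux,
    ca_out, ip3_out, nopen_out,
):
    """Advance the whole microdomain; returns (status, comp, step, clips).

    status 0 = ok, 1 = non-finite state at (comp, step).  ``aux`` holds the
    parent-process (h, ca_er).  kind: 0 node, 1 shaft, 2 parent.
    """
    np.random.seed(seed)
    nc = ca.shape[0]
    N = P[A_N]
    sqdt = math.sqrt(dt)
    jd_ca = np.empty(nc)
    jd_ip = np.empty(nc)
    clips = 0
    s_out = 0
    # record t=0
    for i in range(nc):
        ca_out[s_out, i] = ca[i]
        ip3_out[s_out, i] = ip3[i]
    for no in range(gates.shape[0]):
        nopen_out[s_out, no] = gates[no, 3]
    s_out += 1

    for step in range(n_steps):
        for i in range(nc):
            fca = 0.0
            fip = 0.0
            for k in range(indptr[i], indptr[i + 1]):
                j = indices[k]
                fca += cca[k] * (ca[j] - ca[i])
                fip += cip[k] * (ip3[j] - ip3[i])
            jd_ca[i] = fca
            jd_ip[i] = fip

        for i in range(nc):
            c = ca[i]
            p3 = ip3[i]
            if kind[i] == 0:  # node
                no = node_ord[i]
                al = P[A_A2] * P[A_D2] * (p3 + P[A_D1]) / (p3 + P[A_D3])
                be = P[A_A2] * c
                if deterministic == 1:
                    qq = q[no]
                    po = qq * qq * qq
                    q[no] = qq + dt * (al * (1.0 - qq) - be * qq)
                else:
                    po = gates[no, 3] / N
                    _gate_step(gates[no], al, be, dt)
                caer = (P[A_C0] - c) / P[A_C1]
                minf = p3 / (p3 + P[A_D1])
                ninf = c / (c + P[A_D5])
                mn = minf * ninf
                jchan = P[A_V1] * mn * mn * mn * po * (caer - c)
                jleak = P[A_V2] * (caer - c)
                jser = P[A_V3] * c * c / (c * c + P[A_K3N] * P[A_K3N])
                dca = jchan + jleak - jser + jd_ca[i]
                g03 = glut03[i]
                jpb = P[A_VB] * g03 / (g03 + P[A_KG03])
                jpd = P[A_V4] * (c + (1.0 - P[A_ALPHA]) * P[A_K4]) / (c + P[A_K4])
                dip = jpb + jpd - P[A_TAU] * (p3 - P[A_IP3S]) + jd_ip[i]
            elif kind[i] == 1:  # shaft: diffusion only
                dca = jd_ca[i]
                dip = jd_ip[i]
            else:  # parent
                h = aux[0]
                caer = aux[1]
                al = P[A_A2] * P[A_D2] * (p3 + P[A_D1]) / (p3 + P[A_D3])
                be = P[A_A2] * c
                minf = p3 / (p3 + P[A_D1])
                ninf = c / (c + P[A_D5])
                mn = minf * ninf
                jchan = P[A_V1] * mn * mn * mn * h * h * h * (caer - c)
                jleak = P[A_V2] * (caer - c)
                jser = P[A_V3] * c * c / (c * c + P[A_K3P] * P[A_K3P])
                dca = jchan + jleak - jser + P[A_V5] - P[A_K1] * c + jd_ca[i]
                aux[1] = caer - dt * (jchan + jleak - jser) / P[A_C1]
                g03 = glut03[i]
                jpb = P[A_VB] * g03 / (g03 + P[A_KG03])
                jpd = P[A_V4] * (c + (1.0 - P[A_ALPHA]) * P[A_K4]) / (c + P[A_K4])
                dip = jpb + jpd - P[A_TAU] * (p3 - P[A_IP3S]) + jd_ip[i]
                hn = h + dt * (al * (1.0 - h) - be * h)
                if deterministic == 0 and P[A_SIGH] > 0.0:
                    hn += P[A_SIGH] * sqdt * np.random.normal(0.0, 1.0)
                if hn < 0.0:
                    hn = 0.0
                elif hn > 1.0:
                    hn = 1.0
                aux[0] = hn

            c_new = c + dt * dca
            p_new = p3 + dt * dip
            if c_new < 0.0:
                c_new = 0.0
                clips += 1
            if p_new < 0.0:
                p_new = 0.0
                clips += 1
            ca[i] = c_new
            ip3[i] = p_new

        if (step & 511) == 0:
            for i in range(nc):
                if not (math.isfinite(ca[i]) and math.isfinite(ip3[i])):
                    return 1, i, step, clips
            if not (math.isfinite(aux[0]) and math.isfinite(aux[1])):
                return 1, nc - 1, step, clips

        if (step + 1) % sample_every == 0 and s_out < ca_out.shape[0]:
            for i in range(nc):
                ca_out[s_out, i] = ca[i]
                ip3_out[s_out, i] = ip3[i]
            for no in range(gates.shape[0]):
                nopen_out[s_out, no] = gates[no, 3]
            s_out += 1

    for i in range(nc):
        if not (math.isfinite(ca[i]) and math.isfinite(ip3[i])):
            return 1, i, n_steps - 1, clips
    return 0, -1, -1, clips


# ---------------------------------------------------------------------------
# synapse parameter packing
# ---------------------------------------------------------------------------

(S_CM, S_GK, S_GNA, S_GL, S_VK, S_VNA, S_VL, S_IAPP, S_STIM_ON, S_STIM_OFF,
 S_RHO, S_GCA, S_VCA, S_TAUMCA, S_KAPPA_B, S_VLEAK, S_CAOUT, S_VPM, S_KPM,
 S_VG, S_THETA, S_GAMMA, S_DELTA, S_EPS, S_A1, S_A2S, S_A3, S_VSPONT,
 S_P2, S_TAUREC, S_TAUINACT, S_NV_GV, S_RCLEFT,
 S_K1P, S_K1M, S_K2P, S_K2M, S_K3P, S_K3M, S_CATH,
 S_TAURECA, S_TAUINACTA, S_NVGV_A, S_RAST,
 S_TAUPOST, S_VREST, S_RIN, S_GAMPA, S_VAMPA, S_AAMPA, S_BAMPA,
 S_GNMDA, S_VNMDA, S_ANMDA, S_BNMDA, S_MGO,
 S_ETA, S_LAM, S_KAPPA_S, S_KS, S_THP, S_CREST, S_TAUPRE) = range(63)


@njit(cache=True, inline="always")
def _vtrap(x, y):
    # x/(1-exp(-x/y)) with the removable singularity at x=0 handled
    if abs(x / y) < 1e-6:
        return y + x / 2.0
    return x / (1.0 - math.exp(-x / y))


@njit(cache=True)
def synapse_kernel(
    n_steps, dt, sample_every,
    SP, AP, dca4, dip4, feedback, seed,
    y, gates, out,
):
    """Closed-loop tripartite synapse stepper.

    ``y`` is the packed continuous state (see synapse_model for layout),
    ``gates`` the embedded node's IP3R gate counts, ``dca4``/``dip4`` the
    node-shaft-parent diffusion coefficients in the order
    (node<-shaft, shaft<-node, shaft<-parent, parent<-shaft).
    Returns (status, step, n_evoked, n_spont).
    """
    np.random.seed(seed)
    (Y_V, Y_M, Y_N, Y_H, Y_MCA, Y_CAF, Y_CAS, Y_CAERP, Y_IP3P, Y_HPRE,
     Y_SENS, Y_R, Y_E, Y_GC,
     Y_CAN, Y_IP3N, Y_CASH, Y_IP3SH, Y_CAP, Y_IP3PAR, Y_HPAR, Y_CAERPAR,
     Y_O1, Y_O2, Y_O3, Y_RA, Y_EA, Y_GA,
     Y_VPOST, Y_MA, Y_MN, Y_CPOST) = (
        0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18,
        19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31)

    kg03 = AP[A_KG03]
    glut03_par = 0.0
    # ambient glutamate at the parent process (constant)
    gpar = 1.0
    glut03_par = gpar**0.3

    n_evoked = 0
    n_spont = 0
    s_out = 0
    sens = int(y[Y_SENS])

    for step in range(n_steps):
        t = step * dt
        if s_out < out.shape[0] and step % sample_every == 0:
            out[s_out, 0] = y[Y_V]
            out[s_out, 1] = y[Y_CAF]
            out[s_out, 2] = y[Y_CAS]
            out[s_out, 3] = y[Y_IP3P]
            out[s_out, 4] = y[Y_GC]
            out[s_out, 5] = y[Y_CAN]
            out[s_out, 6] = y[Y_IP3N]
            out[s_out, 7] = y[Y_GA]
            out[s_out, 8] = y[Y_VPOST]
            out[s_out, 9] = y[Y_CPOST]
            out[s_out, 10] = y[Y_R]
            out[s_out, 11] = y[Y_E]
            out[s_out, 12] = y[Y_CAP]
            out[s_out, 13] = gates[3]
            s_out += 1

        # ---- presynaptic membrane (HH), V in mV, rates in 1/s ----
        V = y[Y_V]
        iapp = SP[S_IAPP] if (t >= SP[S_STIM_ON] and t < SP[S_STIM_OFF]) else 0.0
        an = 1000.0 * 0.01 * _vtrap(V + 55.0, 10.0)
        bn = 1000.0 * 0.125 * math.exp(-(V + 65.0) / 80.0)
        am = 1000.0 * 0.1 * _vtrap(V + 40.0, 10.0)
        bm = 1000.0 * 4.0 * math.exp(-(V + 65.0) / 18.0)
        ah = 1000.0 * 0.07 * math.exp(-(V + 65.0) / 20.0)
        bh = 1000.0 / (1.0 + math.exp(-(V + 35.0) / 10.0))
        m = y[Y_M]
        nn_ = y[Y_N]
        hh = y[Y_H]
        ik = SP[S_GK] * nn_**4 * (V - SP[S_VK])
        ina = SP[S_GNA] * m**3 * hh * (V - SP[S_VNA])
        il = SP[S_GL] * (V - SP[S_VL])
        y[Y_V] = V + dt * 1000.0 * (iapp - ik - ina - il) / SP[S_CM]
        y[Y_M] = m + dt * (am * (1.0 - m) - bm * m)
        y[Y_N] = nn_ + dt * (an * (1.0 - nn_) - bn * nn_)
        y[Y_H] = hh + dt * (ah * (1.0 - hh) - bh * hh)

        # ---- presynaptic fast Ca2+ (VGCC + PM leak + PMCA pump) ----
        mca = y[Y_MCA]
        mcainf = 1.0 / (1.0 + math.exp(-(V + 17.0) / 8.3))
        y[Y_MCA] = mca + dt * (mcainf - mca) / SP[S_TAUMCA]
        ica = SP[S_RHO] * SP[S_GCA] * mca * mca * (V - SP[S_VCA])
        jvgcc = -ica * SP[S_KAPPA_B]
        caf = y[Y_CAF]
        jpleak = SP[S_VLEAK] * (SP[S_CAOUT] - caf)
        jpout = -SP[S_VPM] * caf * caf / (caf * caf + SP[S_KPM] * SP[S_KPM])
        caf_new = caf + dt * (jvgcc + jpleak + jpout)

        # ---- presynaptic slow Ca2+ (ER, Li-Rinzel type) ----
        cas = y[Y_CAS]
        ip3p = y[Y_IP3P]
        hpre = y[Y_HPRE]
        caerp = y[Y_CAERP]
        minf = ip3p / (ip3p + AP[A_D1])
        ninf = cas / (cas + AP[A_D5])
        mn = minf * ninf
        jchan = AP[A_V1] * mn * mn * mn * hpre**3 * (caerp - cas)
        jleak = AP[A_V2] * (caerp - cas)
        jser = AP[A_V3] * cas * cas / (cas * cas + AP[A_K3N] * AP[A_K3N])
        dslow = jchan + jleak - jser
        cas_new = cas + dt * dslow
        y[Y_CAERP] = caerp - dt * dslow / AP[A_C1]
        al = AP[A_A2] * AP[A_D2] * (ip3p + AP[A_D1]) / (ip3p + AP[A_D3])
        be = AP[A_A2] * cas
        y[Y_HPRE] = hpre + dt * (al * (1.0 - hpre) - be * hpre)
        ga_eff = y[Y_GA] * feedback
        ga03 = ga_eff**0.3
        drive = SP[S_VG] * ga03 / (ga03 + kg03) if ga_eff > 0.0 else 0.0
        y[Y_IP3P] = ip3p + dt * (drive - SP[S_TAUPRE] * (ip3p - AP[A_IP3S]))

        if caf_new < 0.0:
            caf_new = 0.0
        if cas_new < 0.0:
            cas_new = 0.0
        y[Y_CAF] = caf_new
        y[Y_CAS] = cas_new
        ca_pre = caf_new + cas_new

        # ---- vesicle-fusion sensor chain + spontaneous release ----
        n_ves = 0
        rf = 0.0
        rb = 0.0
        if sens < 5:
            rf = (5 - sens) * SP[S_THETA] * ca_pre
        elif sens == 5:
            rf = SP[S_DELTA]
        if 1 <= sens <= 5:
            rb = sens * SP[S_GAMMA]
        elif sens == 6:
            rb = SP[S_EPS]
        pf = 1.0 - math.exp(-rf * dt)
        pb = 1.0 - math.exp(-rb * dt)
        u = np.random.random()
        if u < pf:
            sens += 1
            if sens == 6:  # fusion-competent isomer reached: evoked release
                n_ves = 1
                if np.random.random() < SP[S_P2]:
                    n_ves = 2
                n_evoked += 1
        elif u < pf + pb:
            sens -= 1
        if y[Y_V] < SP[S_VSPONT]:
            lam = SP[S_A3] / (1.0 + math.exp((SP[S_A1] - ca_pre) / SP[S_A2S]))
            if np.random.random() < 1.0 - math.exp(-lam * dt):
                n_ves += 1
                n_spont += 1

        # ---- presynaptic vesicle pools and cleft glutamate ----
        R = y[Y_R]
        E = y[Y_E]
        Ipool = 1.0 - R - E
        R += dt * Ipool / SP[S_TAUREC]
        E += dt * (-E / SP[S_TAUINACT])
        if n_ves > 0:
            x = (1.0 - math.exp(-float(n_ves))) * R
            R -= x
            E += x
        y[Y_R] = R
        y[Y_E] = E
        gc = y[Y_GC]
        gc_new = gc + dt * (SP[S_NV_GV] * E - SP[S_RCLEFT] * gc)
        if gc_new < 0.0:
            gc_new = 0.0
        y[Y_GC] = gc_new

        # ---- astrocytic node / shaft / parent (microdomain slice) ----
        can = y[Y_CAN]
        ip3n = y[Y_IP3N]
        cash = y[Y_CASH]
        ip3sh = y[Y_IP3SH]
        cap = y[Y_CAP]
        ip3par = y[Y_IP3PAR]
        jd_can = dca4[0] * (cash - can)
        jd_ip3n = dip4[0] * (ip3sh - ip3n)
        jd_cash = dca4[1] * (can - cash) + dca4[2] * (cap - cash)
        jd_ip3sh = dip4[1] * (ip3n - ip3sh) + dip4[2] * (ip3par - ip3sh)
        jd_cap = dca4[3] * (cash - cap)
        jd_ip3par = dip4[3] * (ip3sh - ip3par)

        # node (stochastic IP3R cluster, driven by cleft glutamate)
        aln = AP[A_A2] * AP[A_D2] * (ip3n + AP[A_D1]) / (ip3n + AP[A_D3])
        ben = AP[A_A2] * can
        po = gates[3] / AP[A_N]
        _gate_step(gates, aln, ben, dt)
        caern = (AP[A_C0] - can) / AP[A_C1]
        minf = ip3n / (ip3n + AP[A_D1])
        ninf = can / (can + AP[A_D5])
        mn = minf * ninf
        jchan = AP[A_V1] * mn * mn * mn * po * (caern - can)
        jleak = AP[A_V2] * (caern - can)
        jser = AP[A_V3] * can * can / (can * can + AP[A_K3N] * AP[A_K3N])
        gc03 = gc_new**0.3 if gc_new > 0.0 else 0.0
        jpb = AP[A_VB] * gc03 / (gc03 + kg03) if gc_new > 0.0 else 0.0
        jpd = AP[A_V4] * (can + (1.0 - AP[A_ALPHA]) * AP[A_K4]) / (can + AP[A_K4])
        can_new = can + dt * (jchan + jleak - jser + jd_can)
        ip3n_new = ip3n + dt * (jpb + jpd - AP[A_TAU] * (ip3n - AP[A_IP3S]) + jd_ip3n)

        # shaft (diffusion only)
        y[Y_CASH] = max(cash + dt * jd_cash, 0.0)
        y[Y_IP3SH] = max(ip3sh + dt * jd_ip3sh, 0.0)

        # parent process (deterministic h here; remote from the synapse)
        hpar = y[Y_HPAR]
        caerpar = y[Y_CAERPAR]
        alp = AP[A_A2] * AP[A_D2] * (ip3par + AP[A_D1]) / (ip3par + AP[A_D3])
        bep = AP[A_A2] * cap
        minf = ip3par / (ip3par + AP[A_D1])
        ninf = cap / (cap + AP[A_D5])
        mn = minf * ninf
        jchanp = AP[A_V1] * mn * mn * mn * hpar**3 * (caerpar - cap)
        jleakp = AP[A_V2] * (caerpar - cap)
        jserp = AP[A_V3] * cap * cap / (cap * cap + AP[A_K3P] * AP[A_K3P])
        cap_new = cap + dt * (jchanp + jleakp - jserp + AP[A_V5] - AP[A_K1] * cap + jd_cap)
        y[Y_CAERPAR] = caerpar - dt * (jchanp + jleakp - jserp) / AP[A_C1]
        jpbp = AP[A_VB] * glut03_par / (glut03_par + kg03)
        jpdp = AP[A_V4] * (cap + (1.0 - AP[A_ALPHA]) * AP[A_K4]) / (cap + AP[A_K4])
        y[Y_IP3PAR] = max(
            ip3par + dt * (jpbp + jpdp - AP[A_TAU] * (ip3par - AP[A_IP3S]) + jd_ip3par), 0.0
        )
        hpn = hpar + dt * (alp * (1.0 - hpar) - bep * hpar)
        y[Y_HPAR] = min(max(hpn, 0.0), 1.0)
        y[Y_CAN] = max(can_new, 0.0)
        y[Y_IP3N] = max(ip3n_new, 0.0)
        y[Y_CAP] = max(cap_new, 0.0)

        # ---- astrocytic glutamate release (three gates + pools) ----
        ca_ast = y[Y_CAN]
        for jj in range(3):
            kp = SP[S_K1P + 2 * jj]
            km = SP[S_K1M + 2 * jj]
            o = y[Y_O1 + jj]
            y[Y_O1 + jj] = o + dt * (kp * ca_ast - (kp * ca_ast + km) * o)
        fr_ast = y[Y_O1] * y[Y_O2] * y[Y_O3]
        theta_rel = 1.0 if ca_ast > SP[S_CATH] else 0.0
        Ra = y[Y_RA]
        Ea = y[Y_EA]
        Ia = 1.0 - Ra - Ea
        rel = theta_rel * fr_ast * Ra
        y[Y_RA] = Ra + dt * (Ia / SP[S_TAURECA] - rel)
        y[Y_EA] = Ea + dt * (-Ea / SP[S_TAUINACTA] + rel)
        ga = y[Y_GA]
        y[Y_GA] = max(ga + dt * (SP[S_NVGV_A] * y[Y_EA] - SP[S_RAST] * ga), 0.0)

        # ---- postsynaptic spine ----
        ma = y[Y_MA]
        mnm = y[Y_MN]
        y[Y_MA] = ma + dt * (SP[S_AAMPA] * gc_new * (1.0 - ma) - SP[S_BAMPA] * ma)
        y[Y_MN] = mnm + dt * (SP[S_ANMDA] * gc_new * (1.0 - mnm) - SP[S_BNMDA] * mnm)
        vp = y[Y_VPOST]
        mg = 1.0 / (1.0 + math.exp(-0.062 * vp) * SP[S_MGO] / 3.57)
        i_ampa = SP[S_GAMPA] * ma * (vp - SP[S_VAMPA])
        i_nmda = SP[S_GNMDA] * mnm * mg * (vp - SP[S_VNMDA])
        y[Y_VPOST] = vp + dt * (-(vp - SP[S_VREST]) - SP[S_RIN] * (i_ampa + i_nmda)) / SP[S_TAUPOST]
        cp = y[Y_CPOST]
        dcp = (
            -(SP[S_ETA] * i_ampa + SP[S_LAM] * i_nmda) * SP[S_KAPPA_S]
            - SP[S_KS] * (cp - SP[S_CREST])
        ) / (1.0 + SP[S_THP])
        y[Y_CPOST] = max(cp + dt * dcp, 0.0)

        if (step & 1023) == 0:
            ok = True
            for kk in range(32):
                if not math.isfinite(y[kk]):
                    ok = False
            if not ok:
                y[Y_SENS] = sens
                return 1, step, n_evoked, n_spont

    y[Y_SENS] = sens
    for kk in range(32):
        if not math.isfinite(y[kk]):
            return 1, n_steps - 1, n_evoked, n_spont
    return 0, -1, n_evoked, n_spont
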