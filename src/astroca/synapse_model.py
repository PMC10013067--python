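"""Tripartite synapse: bouton, cleft, astrocytic node and spine.

The signalling chain is: Hodgkin-Huxley action potentials open presynaptic
voltage-gated Ca2+ channels; a five-site Ca2+ sensor (plus a Poisson
spontaneous pathway active only when the membrane is not depolarized)
triggers vesicle fusion; cleft glutamate (i) gates postsynaptic AMPA and
NMDA receptors (with voltage-dependent Mg2+ block) and (ii) drives IP3
production in the enwrapping astrocytic node, whose Ca2+ elevations open
a three-gate release machinery that puts glutamate back onto presynaptic
metabotropic receptors, closing the loop through the bouton's ER Ca2+
store.  The astrocytic compartment is a node-shaft-parent slice of the
microdomain model, so its geometry (and hence atrophy of the node) feeds
straight into synaptic transmission.

The rate constants printed in the published parameter table (NMDA gating,
Mg2+ block, the two fractional-current scale factors) are fixed defaults
here.  The remaining constants are deferred by the source to earlier
bouton/sensor modelling work and are shipped as a documented,
individually overridable default set; see each field's comment for its
provenance and the package methods note for the calibration rationale.

Units: mV, s, uM; conductances nS; currents pA (spine) or uA/cm^2
(bouton membrane).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

from . import _kernels
from .errors import IntegrationError, InvalidStepError
from .morphology import Geometry, build_chain_model
from .params import AstroParams
from .traces import TraceSet

__all__ = [
    "SynapseParams",
    "SynapseState",
    "FARADAY",
    "hh_rates",
    "presyn_membrane_step",
    "presyn_ca_step",
    "sensor_transition_rates",
    "release_chain_step",
    "spontaneous_rate",
    "vesicle_pools_step",
    "cleft_glutamate_step",
    "astro_release_step",
    "mg_block",
    "postsyn_step",
    "simulate_tripartite",
]

FARADAY = 96487.0  # C/mol


@dataclass(frozen=True)
class SynapseParams:
    # --- presynaptic membrane (standard squid-type HH; uA/cm^2, mS/cm^2) ---
    c_m: float = 1.0          # membrane capacitance [uF/cm^2]
    g_k: float = 36.0         # delayed-rectifier K+ conductance [mS/cm^2]
    g_na: float = 120.0       # Na+ conductance [mS/cm^2]
    g_l: float = 0.3          # leak conductance [mS/cm^2]
    v_k: float = -77.0        # [mV]
    v_na: float = 50.0        # [mV]
    v_l: float = -54.4        # [mV]
    i_app: float = 10.0       # constant stimulation current [uA/cm^2]
    stim_on: float = 1.0      # stimulation window start [s]
    stim_off: float = 1e9     # stimulation window end [s]

    # --- presynaptic N-type VGCC and Ca2+ handling ---
    rho_ca: float = 0.5       # channel density scale (dimensionless)
    g_ca: float = 1.0         # VGCC conductance [mS/cm^2]
    v_ca: float = 125.0       # Ca2+ Nernst potential [mV]
    tau_mca: float = 1e-3     # VGCC activation time constant [s]
    a_bouton: float = 4.52    # bouton surface [um^2] (0.6 um-radius sphere)
    v_bouton: float = 0.905   # bouton volume [um^3]
    z_ca: int = 2
    v_leak_pre: float = 0.01  # PM leak [1/s]; balances the pump at rest
    ca_out: float = 2000.0    # extracellular Ca2+ [uM]
    v_pmca: float = 8000.0    # PMCA max flux [uM/s]; clears the spike
                              # transient within ~2 ms so release stays
                              # spike-locked at sustained firing
    k_pmca: float = 2.0       # PMCA half-activation [uM]
    v_g: float = 0.2          # astro-glutamate -> presyn IP3 drive [uM/s]
    tau_ip3_pre_inv: float = 0.14  # bouton IP3 loss rate [1/s] (printed value;
                              # self-consistent here: production <= v_g)

    # --- five-site vesicle fusion sensor (fast, low-affinity; per-site
    #     Kd = gamma/theta = 10 uM as in fast-sensor bouton models) ---
    theta: float = 300.0      # Ca2+ association [1/(uM s)]
    gamma: float = 3000.0     # Ca2+ dissociation [1/s]
    delta: float = 4000.0     # X5 -> X5* isomerization [1/s]
    epsilon: float = 2000.0   # X5* -> X5 [1/s]
    a1: float = 0.8           # spontaneous-release half point [uM];
                              # centered on the feedback-elevated Ca2+ range
    a2_star: float = 0.1      # spontaneous-release slope [uM]
    a3: float = 2.0           # spontaneous-release max rate [1/s]
    v_spont_max: float = -60.0  # "not depolarized" cutoff [mV]
    p_two: float = 0.25       # probability an evoked event carries 2 vesicles
    release_scale: float = 1.0  # scales evoked+spontaneous release probability

    # --- vesicle pools and cleft glutamate ---
    tau_rec: float = 0.8      # recovery of releasable pool [s]
    tau_inact: float = 3e-3   # effective (cleft-facing) pool decay [s]
    n_v: float = 4.0          # docked vesicles per release site
    g_v: float = 1.5e5        # glutamate release rate scale [uM/s];
                              # one fusion drives the cleft to ~0.1-0.5 mM
    r_cleft: float = 100.0    # cleft glutamate clearance [1/s]

    # --- astrocytic release gates and pools ---
    k1_plus: float = 3.75     # gate 1 opening [1/(uM s)]
    k1_minus: float = 0.4     # gate 1 closing [1/s]
    k2_plus: float = 2.5
    k2_minus: float = 1.0
    k3_plus: float = 5.0
    k3_minus: float = 10.0
    ca_ast_th: float = 0.19669  # gliotransmission Ca2+ threshold [uM]
    tau_rec_ast: float = 0.8
    tau_inact_ast: float = 0.3
    n_v_ast: float = 12.0
    g_v_ast: float = 65.0     # [uM/s]; keeps extrasynaptic glutamate in
                              # the sensitive range of k_g
    r_ast: float = 10.0       # extrasynaptic glutamate clearance [1/s]

    # --- postsynaptic spine ---
    tau_post: float = 0.02    # membrane time constant [s]
    v_post_rest: float = -70.0  # [mV]
    r_m: float = 1.0          # membrane resistance density [GOhm/um^2]
    a_spine: float = 0.5      # spine area [um^2]; r_m*a_spine = input R [GOhm]
    g_ampa: float = 0.35      # [nS]
    v_ampa: float = 0.0       # [mV]
    alpha_ampa: float = 1.1   # AMPA opening [1/(uM s)]
    beta_ampa: float = 190.0  # AMPA closing [1/s]
    g_nmda: float = 0.3       # [nS], printed admissible range 0.01-0.6
    v_nmda: float = 0.0       # [mV] (printed)
    alpha_nmda: float = 2.2   # NMDA opening [1/(uM s)] (printed)
    beta_nmda: float = 0.67   # NMDA closing [1/s] (printed)
    mg_out: float = 1.0       # [mM], printed admissible range 1-2
    eta: float = 0.012        # AMPA fractional Ca2+ current scale (printed)
    lam: float = 0.12         # NMDA fractional Ca2+ current scale (printed)
    v_spine: float = 0.06     # spine head volume [um^3]
    k_s: float = 7000.0       # spine Ca2+ extrusion [1/s]
    theta_post: float = 100.0  # rapid-buffer capacity (dimensionless)
    c_post_rest: float = 0.05  # resting spine Ca2+ [uM]

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("v_k", "v_na", "v_l", "v_ca", "v_ampa", "v_nmda",
                          "v_post_rest", "v_spont_max", "stim_on", "stim_off"):
                continue
            if v < 0:
                raise ValueError(f"{f.name} must be nonnegative")

    def with_(self, **kwargs) -> "SynapseParams":
        return replace(self, **kwargs)

    @property
    def kappa_bouton(self) -> float:
        """Current-to-flux conversion A/(z F V): uM/s per uA/cm^2."""
        area_cm2 = self.a_bouton * 1e-8
        vol_l = self.v_bouton * 1e-15
        return area_cm2 / (self.z_ca * FARADAY * vol_l) * 1e-6 * 1e6

    @property
    def kappa_spine(self) -> float:
        """Current-to-flux conversion 1/(z F V): uM/s per pA."""
        vol_l = self.v_spine * 1e-15
        return 1e-12 / (self.z_ca * FARADAY * vol_l) * 1e6


def _pack_synapse(p: SynapseParams) -> np.ndarray:
    K = _kernels
    out = np.zeros(63)
    out[K.S_CM] = p.c_m
    out[K.S_GK] = p.g_k
    out[K.S_GNA] = p.g_na
    out[K.S_GL] = p.g_l
    out[K.S_VK] = p.v_k
    out[K.S_VNA] = p.v_na
    out[K.S_VL] = p.v_l
    out[K.S_IAPP] = p.i_app
    out[K.S_STIM_ON] = p.stim_on
    out[K.S_STIM_OFF] = p.stim_off
    out[K.S_RHO] = p.rho_ca
    out[K.S_GCA] = p.g_ca
    out[K.S_VCA] = p.v_ca
    out[K.S_TAUMCA] = p.tau_mca
    out[K.S_KAPPA_B] = p.kappa_bouton
    out[K.S_VLEAK] = p.v_leak_pre
    out[K.S_CAOUT] = p.ca_out
    out[K.S_VPM] = p.v_pmca
    out[K.S_KPM] = p.k_pmca
    out[K.S_VG] = p.v_g
    out[K.S_THETA] = p.theta
    out[K.S_GAMMA] = p.gamma
    out[K.S_DELTA] = p.delta * p.release_scale
    out[K.S_EPS] = p.epsilon
    out[K.S_A1] = p.a1
    out[K.S_A2S] = p.a2_star
    out[K.S_A3] = p.a3 * p.release_scale
    out[K.S_VSPONT] = p.v_spont_max
    out[K.S_P2] = p.p_two
    out[K.S_TAUREC] = p.tau_rec
    out[K.S_TAUINACT] = p.tau_inact
    out[K.S_NV_GV] = p.n_v * p.g_v
    out[K.S_RCLEFT] = p.r_cleft
    out[K.S_K1P] = p.k1_plus
    out[K.S_K1M] = p.k1_minus
    out[K.S_K2P] = p.k2_plus
    out[K.S_K2M] = p.k2_minus
    out[K.S_K3P] = p.k3_plus
    out[K.S_K3M] = p.k3_minus
    out[K.S_CATH] = p.ca_ast_th
    out[K.S_TAURECA] = p.tau_rec_ast
    out[K.S_TAUINACTA] = p.tau_inact_ast
    out[K.S_NVGV_A] = p.n_v_ast * p.g_v_ast
    out[K.S_RAST] = p.r_ast
    out[K.S_TAUPOST] = p.tau_post
    out[K.S_VREST] = p.v_post_rest
    out[K.S_RIN] = p.r_m * p.a_spine
    out[K.S_GAMPA] = p.g_ampa
    out[K.S_VAMPA] = p.v_ampa
    out[K.S_AAMPA] = p.alpha_ampa
    out[K.S_BAMPA] = p.beta_ampa
    out[K.S_GNMDA] = p.g_nmda
    out[K.S_VNMDA] = p.v_nmda
    out[K.S_ANMDA] = p.alpha_nmda
    out[K.S_BNMDA] = p.beta_nmda
    out[K.S_MGO] = p.mg_out
    out[K.S_ETA] = p.eta
    out[K.S_LAM] = p.lam
    out[K.S_KAPPA_S] = p.kappa_spine
    out[K.S_KS] = p.k_s
    out[K.S_THP] = p.theta_post
    out[K.S_CREST] = p.c_post_rest
    out[K.S_TAUPRE] = p.tau_ip3_pre_inv
    return out


# ---------------------------------------------------------------------------
# Reference step functions (scalar; the compiled kernel is the fast path)
# ---------------------------------------------------------------------------


def hh_rates(v: float) -> tuple[float, ...]:
    """Standard HH gate rate functions (alpha_m, beta_m, alpha_n, beta_n,
    alpha_h, beta_h) in 1/s at membrane potential v [mV]."""

    def vtrap(x, y):
        if abs(x / y) < 1e-6:
            return y + x / 2.0
        return x / (1.0 - math.exp(-x / y))

    am = 1000.0 * 0.1 * vtrap(v + 40.0, 10.0)
    bm = 1000.0 * 4.0 * math.exp(-(v + 65.0) / 18.0)
    an = 1000.0 * 0.01 * vtrap(v + 55.0, 10.0)
    bn = 1000.0 * 0.125 * math.exp(-(v + 65.0) / 80.0)
    ah = 1000.0 * 0.07 * math.exp(-(v + 65.0) / 20.0)
    bh = 1000.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
    return am, bm, an, bn, ah, bh


def presyn_membrane_step(
    v: float, m: float, n: float, h: float, p: SynapseParams, dt: float,
    i_app: float | None = None,
) -> tuple[float, float, float, float]:
    """One Euler step of the presynaptic HH membrane."""
    if dt <= 0:
        raise InvalidStepError(f"dt must be positive, got {dt}")
    i = p.i_app if i_app is None else i_app
    am, bm, an, bn, ah, bh = hh_rates(v)
    i_ion = (
        p.g_k * n**4 * (v - p.v_k)
        + p.g_na * m**3 * h * (v - p.v_na)
        + p.g_l * (v - p.v_l)
    )
    v2 = v + dt * 1000.0 * (i - i_ion) / p.c_m
    m2 = m + dt * (am * (1 - m) - bm * m)
    n2 = n + dt * (an * (1 - n) - bn * n)
    h2 = h + dt * (ah * (1 - h) - bh * h)
    return v2, m2, n2, h2


def hh_resting_state(p: SynapseParams, v: float = -65.0) -> tuple[float, float, float]:
    """Steady-state HH gates (m, n, h) at potential v."""
    am, bm, an, bn, ah, bh = hh_rates(v)
    return am / (am + bm), an / (an + bn), ah / (ah + bh)


def presyn_ca_step(
    v: float,
    m_ca: float,
    ca_fast: float,
    ca_slow: float,
    ca_er: float,
    ip3: float,
    h_er: float,
    g_ast: float,
    p: SynapseParams,
    ap: AstroParams,
    dt: float,
) -> tuple[float, float, float, float, float, float]:
    """One Euler step of the two presynaptic Ca2+ pools.

    The fast pool is fed by the VGCC current (converted to a flux with the
    bouton surface/volume factor) and drained by the PMCA pump; the slow
    pool exchanges with the bouton ER with IP3 driven by astrocytic
    glutamate.  Returns (m_ca, ca_fast, ca_slow, ca_er, ip3, h_er).
    """
    if dt <= 0:
        raise InvalidStepError(f"dt must be positive, got {dt}")
    mca_inf = 1.0 / (1.0 + math.exp(-(v + 17.0) / 8.3))
    m_ca2 = m_ca + dt * (mca_inf - m_ca) / p.tau_mca
    i_ca = p.rho_ca * p.g_ca * m_ca**2 * (v - p.v_ca)
    j_vgcc = -i_ca * p.kappa_bouton
    j_leak_pm = p.v_leak_pre * (p.ca_out - ca_fast)
    j_out = -p.v_pmca * ca_fast**2 / (ca_fast**2 + p.k_pmca**2)
    ca_fast2 = max(ca_fast + dt * (j_vgcc + j_leak_pm + j_out), 0.0)

    m_inf = ip3 / (ip3 + ap.d1)
    n_inf = ca_slow / (ca_slow + ap.d5)
    j_chan = ap.v1 * m_inf**3 * n_inf**3 * h_er**3 * (ca_er - ca_slow)
    j_leak = ap.v2 * (ca_er - ca_slow)
    j_serca = ap.v3 * ca_slow**2 / (ca_slow**2 + ap.k3_node**2)
    d_slow = j_chan + j_leak - j_serca
    ca_slow2 = max(ca_slow + dt * d_slow, 0.0)
    ca_er2 = ca_er - dt * d_slow / ap.c1
    alpha = ap.a2 * ap.d2 * (ip3 + ap.d1) / (ip3 + ap.d3)
    beta = ap.a2 * ca_slow
    h_er2 = h_er + dt * (alpha * (1 - h_er) - beta * h_er)
    if g_ast > 0:
        ga03 = g_ast**0.3
        drive = p.v_g * ga03 / (ga03 + ap.k_g**0.3)
    else:
        drive = 0.0
    ip3_2 = ip3 + dt * (drive - p.tau_ip3_pre_inv * (ip3 - ap.ip3_star))
    return m_ca2, ca_fast2, ca_slow2, ca_er2, ip3_2, h_er2


def sensor_transition_rates(state: int, ca: float, p: SynapseParams) -> tuple[float, float]:
    """(forward, backward) rates out of a sensor state 0..6.

    States 0..5 are the Ca2+ sensor with 0..5 ions bound; state 6 is the
    fusion-competent isomer X5*.
    """
    fwd = bwd = 0.0
    if state < 5:
        fwd = (5 - state) * p.theta * ca
    elif state == 5:
        fwd = p.delta * p.release_scale
    if 1 <= state <= 5:
        bwd = state * p.gamma
    elif state == 6:
        bwd = p.epsilon
    return fwd, bwd


def release_chain_step(
    state: int, ca: float, p: SynapseParams, dt: float, rng: np.random.Generator
) -> tuple[int, bool]:
    """One exact-probability jump of the sensor; True when fusion fires
    (i.e. the chain just reached the fusion-competent isomer)."""
    if dt <= 0:
        raise InvalidStepError(f"dt must be positive, got {dt}")
    fwd, bwd = sensor_transition_rates(state, ca, p)
    pf = 1.0 - math.exp(-fwd * dt)
    pb = 1.0 - math.exp(-bwd * dt)
    u = rng.random()
    if u < pf:
        return state + 1, state + 1 == 6
    if u < pf + pb:
        return state - 1, False
    return state, False


def spontaneous_rate(ca: float, p: SynapseParams) -> float:
    """Poisson rate of spontaneous vesicle release [1/s], sigmoidal in Ca2+
    with supremum a3 (times the release probability scale)."""
    return p.a3 * p.release_scale / (1.0 + math.exp((p.a1 - ca) / p.a2_star))


def vesicle_pools_step(
    r: float, e: float, f_r: float, p: SynapseParams, dt: float
) -> tuple[float, float, float]:
    """Releasable/effective/inactive pool update; returns (R, E, I).

    ``f_r`` is the instantaneous release rate [1/s]; an n-vesicle fusion
    event in one step corresponds to f_r = n/dt, integrated exactly over
    the step so the transferred fraction is 1 - exp(-f_r*dt).
    """
    if dt <= 0:
        raise InvalidStepError(f"dt must be positive, got {dt}")
    i = 1.0 - r - e
    if i < -1e-9 or r < -1e-9 or e < -1e-9:
        raise ValueError("vesicle pools left the simplex")
    x = (1.0 - math.exp(-f_r * dt)) * r
    r2 = r + dt * i / p.tau_rec - x
    e2 = e - dt * e / p.tau_inact + x
    return r2, e2, 1.0 - r2 - e2


def cleft_glutamate_step(g: float, e: float, p: SynapseParams, dt: float) -> float:
    """Cleft glutamate: vesicular source n_v*g_v*E minus clearance r*g."""
    if dt <= 0:
        raise InvalidStepError(f"dt must be positive, got {dt}")
    return g + dt * (p.n_v * p.g_v * e - p.r_cleft * g)


def astro_release_step(
    o: tuple[float, float, float],
    r_ast: float,
    e_ast: float,
    g_ast: float,
    ca_ast: float,
    p: SynapseParams,
    dt: float,
) -> tuple[tuple[float, float, float], float, float, float]:
    """Astrocytic release gates, pools and extrasynaptic glutamate.

    Release requires all three Ca2+-gated sites open *and* node Ca2+ above
    the gliotransmission threshold (Heaviside gate).
    """
    if dt <= 0:
        raise InvalidStepError(f"dt must be positive, got {dt}")
    kp = (p.k1_plus, p.k2_plus, p.k3_plus)
    km = (p.k1_minus, p.k2_minus, p.k3_minus)
    o2 = tuple(
        oj + dt * (kpj * ca_ast - (kpj * ca_ast + kmj) * oj)
        for oj, kpj, kmj in zip(o, kp, km)
    )
    f_r = o[0] * o[1] * o[2] if ca_ast > p.ca_ast_th else 0.0
    i_ast = 1.0 - r_ast - e_ast
    r2 = r_ast + dt * (i_ast / p.tau_rec_ast - f_r * r_ast)
    e2 = e_ast + dt * (-e_ast / p.tau_inact_ast + f_r * r_ast)
    g2 = g_ast + dt * (p.n_v_ast * p.g_v_ast * e_ast - p.r_ast * g_ast)
    return o2, r2, e2, g2


def mg_block(v: float, p: SynapseParams) -> float:
    """Voltage-dependent Mg2+ block of the NMDA receptor, in (0, 1)."""
    return 1.0 / (1.0 + math.exp(-0.062 * v) * p.mg_out / 3.57)


def postsyn_step(
    v: float,
    m_ampa: float,
    m_nmda: float,
    c: float,
    g_cleft: float,
    p: SynapseParams,
    dt: float,
) -> tuple[float, float, float, float]:
    """Postsynaptic spine update: receptor gates, potential, Ca2+."""
    if dt <= 0:
        raise InvalidStepError(f"dt must be positive, got {dt}")
    ma2 = m_ampa + dt * (p.alpha_ampa * g_cleft * (1 - m_ampa) - p.beta_ampa * m_ampa)
    mn2 = m_nmda + dt * (p.alpha_nmda * g_cleft * (1 - m_nmda) - p.beta_nmda * m_nmda)
    i_ampa = p.g_ampa * m_ampa * (v - p.v_ampa)
    i_nmda = p.g_nmda * m_nmda * mg_block(v, p) * (v - p.v_nmda)
    v2 = v + dt * (-(v - p.v_post_rest) - p.r_m * p.a_spine * (i_ampa + i_nmda)) / p.tau_post
    dc = (
        -(p.eta * i_ampa + p.lam * i_nmda) * p.kappa_spine
        - p.k_s * (c - p.c_post_rest)
    ) / (1.0 + p.theta_post)
    c2 = max(c + dt * dc, 0.0)
    return v2, ma2, mn2, c2


# ---------------------------------------------------------------------------
# Full closed-loop simulator
# ---------------------------------------------------------------------------

_TRACE_COLUMNS = [
    "v_pre", "ca_fast", "ca_slow", "ip3_pre", "g_cleft", "ca_node",
    "ip3_node", "g_ast", "v_post", "c_post", "R", "E", "ca_parent", "n_open",
]


@dataclass
class SynapseState:
    """Packed continuous state of the tripartite synapse (kernel layout)."""

    y: np.ndarray
    gates: np.ndarray

    @staticmethod
    def initial(p: SynapseParams, ap: AstroParams) -> "SynapseState":
        from .astro_model import gate_rates, initial_gate_counts

        y = np.zeros(32)
        v0 = -65.0
        m0, n0, h0 = hh_resting_state(p, v0)
        ca0 = 0.1
        al, be = gate_rates(ca0, ap.ip3_star, ap)
        q0 = al / (al + be)
        y[0] = v0
        y[1], y[2], y[3] = m0, n0, h0
        y[4] = 1.0 / (1.0 + math.exp(-(v0 + 17.0) / 8.3))
        y[5] = ca0                      # ca_fast
        y[6] = ca0                      # ca_slow
        y[7] = (ap.c0 - ca0) / ap.c1    # bouton ER
        y[8] = ap.ip3_star              # ip3_pre
        y[9] = q0                       # h_pre
        y[10] = 0                       # sensor state
        y[11] = 1.0                     # R
        y[12] = 0.0                     # E
        y[13] = 0.0                     # g_cleft
        y[14] = ca0                     # node ca
        y[15] = ap.ip3_star
        y[16] = ca0                     # shaft
        y[17] = ap.ip3_star
        y[18] = ca0                     # parent
        y[19] = ap.ip3_star
        y[20] = q0                      # parent h
        y[21] = (ap.c0 - ca0) / ap.c1
        y[22] = y[23] = y[24] = 0.0     # O1..O3
        y[25] = 1.0                     # R_ast
        y[26] = 0.0                     # E_ast
        y[27] = 0.0                     # g_ast
        y[28] = p.v_post_rest
        y[29] = y[30] = 0.0             # m_AMPA, m_NMDA
        y[31] = p.c_post_rest
        return SynapseState(y=y, gates=initial_gate_counts(ca0, ap.ip3_star, ap))


def _astro_couplings(geom: Geometry, ap: AstroParams):
    """Diffusion coefficients of the embedded node-shaft-parent slice."""
    g = build_chain_model(1, geom)
    node, shaft = "n1", "s_n1_parent"
    pairs = [(node, shaft), (shaft, node), (shaft, "parent"), ("parent", shaft)]
    dca = np.array([g.coupling_coefficient(i, j, ap.d_ca) for i, j in pairs])
    dip = np.array([g.coupling_coefficient(i, j, ap.d_ip3) for i, j in pairs])
    return dca, dip


def simulate_tripartite(
    params: SynapseParams | None = None,
    astro_params: AstroParams | None = None,
    astro_geom: Geometry | None = None,
    duration: float = 20.0,
    dt: float = 1e-5,
    seed: int = 0,
    trials: int = 1,
    burn_in: float = 1.0,
    sample_every: int = 50,
    astro_feedback: bool = True,
) -> TraceSet:
    """Simulate the closed-loop tripartite synapse.

    ``astro_geom`` sets the enwrapping microdomain slice (reduce
    ``w_node`` to model atrophy).  ``astro_feedback=False`` severs the
    astrocyte-dependent pathway by forcing the glutamate seen by the
    presynaptic terminal to zero (gliotransmitter release still happens
    and is recorded).
    """
    p = params or SynapseParams()
    ap = astro_params if astro_params is not None else AstroParams.calibrated()
    geom = astro_geom or Geometry()
    if dt <= 0:
        raise InvalidStepError(f"dt must be positive, got {dt}")
    sp = _pack_synapse(p)
    apk = _kernels.pack_astro(ap)
    dca4, dip4 = _astro_couplings(geom, ap)

    n_steps = int(round(duration / dt))
    nsamp = (n_steps - 1) // sample_every + 1
    time = np.arange(nsamp) * (dt * sample_every)
    ncol = len(_TRACE_COLUMNS)
    all_out = np.empty((trials, nsamp, ncol))
    events = []

    ss = np.random.SeedSequence(seed)
    for t, child in enumerate(ss.spawn(trials)):
        st = SynapseState.initial(p, ap)
        out = np.empty((nsamp, ncol))
        kseed = int(child.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
        status, step, n_evoked, n_spont = _kernels.synapse_kernel(
            n_steps, dt, sample_every,
            sp, apk, dca4, dip4, 1.0 if astro_feedback else 0.0, kseed,
            st.y, st.gates, out,
        )
        if status != 0:
            raise IntegrationError("synapse", float(step) * dt)
        all_out[t] = out
        events.append({"evoked": int(n_evoked), "spontaneous": int(n_spont)})

    data = {name: all_out[:, :, [j]] for j, name in enumerate(_TRACE_COLUMNS)}
    columns = {name: [name] for name in _TRACE_COLUMNS}
    return TraceSet(
        time=time,
        data=data,
        columns=columns,
        meta={
            "seed": seed,
            "dt": dt,
            "duration": duration,
            "burn_in": burn_in,
            "trials": trials,
            "astro_feedback": astro_feedback,
            "events": events,
            "geometry": geom.__dict__.copy(),
        },
    )
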