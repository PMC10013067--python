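"""Stochastic Ca2+/IP3 dynamics on the compartment graph.

Nodes carry a cluster of ``N`` IP3R channels, each with three stochastic
h-gates advanced by a Markov jump chain with exact exponential transition
probabilities; a channel conducts only when all three gates are open, and
the instantaneous open fraction ``n_open/N`` replaces the deterministic
h-cube of the classic two-variable IP3R reduction.  The parent process
keeps the continuous gating variable h, driven by a Wiener noise term.
Shafts are organelle-free and purely diffusive.  The module exposes the
individual flux terms (useful for testing against closed forms) and the
fixed-step Euler-Maruyama simulator that assembles them on a graph.

Units: concentrations in uM, time in s, lengths in um.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from . import _kernels
from .errors import IntegrationError, InvalidStepError
from .morphology import CompartmentGraph, Kind
from .params import AstroParams
from .traces import TraceSet

__all__ = [
    "gate_rates",
    "node_ca_rhs",
    "node_ip3_rhs",
    "parent_rhs",
    "markov_gate_step",
    "gate_stationary_pmf",
    "diffusion_fluxes",
    "simulate_astro",
    "simulate_gate_chain",
    "astro_ode_rhs",
    "initial_gate_counts",
    "CLIP_FRACTION_LIMIT",
]

#: A run clipping more than this fraction of its Euler steps to zero
#: concentration is considered numerically unsound.
CLIP_FRACTION_LIMIT = 1e-3


# ---------------------------------------------------------------------------
# Flux terms (scalar reference implementations)
# ---------------------------------------------------------------------------


def gate_rates(ca: float, ip3: float, p: AstroParams) -> tuple[float, float]:
    """Per-gate opening and closing rates (alpha_h, beta_h) in 1/s."""
    alpha = p.a2 * p.d2 * (ip3 + p.d1) / (ip3 + p.d3)
    beta = p.a2 * ca
    return alpha, beta


def _plc_beta(glut: float, p: AstroParams) -> float:
    if glut <= 0:
        return 0.0
    g03 = glut**0.3
    return p.v_beta * g03 / (g03 + p.k_g**0.3)


def _plc_delta(ca: float, p: AstroParams) -> float:
    return p.v4 * (ca + (1.0 - p.alpha) * p.k4) / (ca + p.k4)


def node_ca_rhs(
    ca: float, ip3: float, n_open: int, p: AstroParams, j_diff: float = 0.0
) -> float:
    """d[Ca2+]/dt in a node (uM/s).

    ER Ca2+ is the algebraic pool (c0 - ca)/c1; the channel flux scales
    with the stochastic open fraction n_open/N.
    """
    ca_er = (p.c0 - ca) / p.c1
    m_inf = ip3 / (ip3 + p.d1)
    n_inf = ca / (ca + p.d5)
    j_chan = p.v1 * m_inf**3 * n_inf**3 * (n_open / p.N) * (ca_er - ca)
    j_leak = p.v2 * (ca_er - ca)
    j_serca = p.v3 * ca**2 / (ca**2 + p.k3_node**2)
    return j_chan + j_leak - j_serca + j_diff


def node_ip3_rhs(
    ca: float,
    ip3: float,
    p: AstroParams,
    glut: float | None = None,
    j_diff: float = 0.0,
) -> float:
    """d[IP3]/dt in a node (uM/s); glutamate defaults to the ambient level."""
    g = p.g if glut is None else glut
    return (
        _plc_beta(g, p)
        + _plc_delta(ca, p)
        - p.tau_ip3_inv * (ip3 - p.ip3_star)
        + j_diff
    )


def parent_rhs(
    ca: float,
    ca_er: float,
    ip3: float,
    h: float,
    p: AstroParams,
    j_diff_ca: float = 0.0,
    j_diff_ip3: float = 0.0,
    glut: float | None = None,
) -> tuple[float, float, float, float]:
    """Drift of (ca, ca_er, ip3, h) in the parent process.

    The Wiener term sigma_h*dW on h is added by the integrator; this
    returns the deterministic part only.  Ca2+ extrusion is an efflux
    (-k1*ca) and the ER balance mirrors the cytosolic exchange with the
    opposite sign, scaled by the volume ratio c1.
    """
    m_inf = ip3 / (ip3 + p.d1)
    n_inf = ca / (ca + p.d5)
    j_chan = p.v1 * m_inf**3 * n_inf**3 * h**3 * (ca_er - ca)
    j_leak = p.v2 * (ca_er - ca)
    j_serca = p.v3 * ca**2 / (ca**2 + p.k3_parent**2)
    d_ca = j_chan + j_leak - j_serca + p.v5 - p.k1 * ca + j_diff_ca
    d_ca_er = -(j_chan + j_leak - j_serca) / p.c1
    g = p.g if glut is None else glut
    d_ip3 = (
        _plc_beta(g, p)
        + _plc_delta(ca, p)
        - p.tau_ip3_inv * (ip3 - p.ip3_star)
        + j_diff_ip3
    )
    alpha, beta = gate_rates(ca, ip3, p)
    d_h = alpha * (1.0 - h) - beta * h
    return d_ca, d_ca_er, d_ip3, d_h


# ---------------------------------------------------------------------------
# Markov IP3R gate chain
# ---------------------------------------------------------------------------


def markov_gate_step(
    counts: np.ndarray,
    ca: float,
    ip3: float,
    dt: float,
    p: AstroParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance the gate-count chain one step; returns the new counts.

    ``counts[i]`` is the number of channels with i open h-gates
    (sum = N); a channel is conducting when all three are open.  Each
    channel jumps at most once per step, with exact exponential
    probabilities 1 - exp(-rate*dt); e.g. a channel with one open gate
    opens another with probability 1 - exp(-2*alpha_h*dt) and closes it
    with probability 1 - exp(-beta_h*dt).
    """
    if dt <= 0:
        raise InvalidStepError(f"dt must be positive, got {dt}")
    counts = np.asarray(counts, dtype=np.int64).copy()
    alpha, beta = gate_rates(ca, ip3, p)
    ea = math.exp(-alpha * dt)
    eb = math.exp(-beta * dt)
    delta = np.zeros(4, dtype=np.int64)
    for i in range(4):
        n_i = int(counts[i])
        if n_i == 0:
            continue
        p_up = 1.0 - ea ** (3 - i) if i < 3 else 0.0
        p_down = 1.0 - eb**i if i > 0 else 0.0
        p_move = p_up + p_down
        if p_move <= 0:
            continue
        movers = rng.binomial(n_i, p_move)
        up = rng.binomial(movers, p_up / p_move) if movers else 0
        down = movers - up
        delta[i] -= movers
        if up:
            delta[i + 1] += up
        if down:
            delta[i - 1] += down
    counts += delta
    return counts


def gate_stationary_pmf(ca: float, ip3: float, p: AstroParams) -> np.ndarray:
    """Stationary law of a single channel's gate count: Binomial(3, p_open).

    Each h-gate is an independent two-state process, open with
    probability alpha_h/(alpha_h+beta_h) at stationarity.
    """
    alpha, beta = gate_rates(ca, ip3, p)
    q = alpha / (alpha + beta)
    k = np.arange(4)
    return np.array([math.comb(3, int(i)) for i in k]) * q**k * (1 - q) ** (3 - k)


def simulate_gate_chain(
    ca: float,
    ip3: float,
    p: AstroParams,
    n_channels: int,
    dt: float,
    n_steps: int,
    seed: int,
    burn_steps: int = 0,
    sample_every: int = 1,
) -> np.ndarray:
    """Clamped-(ca, ip3) gate chain; returns sampled counts (n_samples, 4)."""
    if dt <= 0:
        raise InvalidStepError(f"dt must be positive, got {dt}")
    alpha, beta = gate_rates(ca, ip3, p)
    counts = initial_gate_counts(ca, ip3, p, n_channels)
    return _kernels.gate_chain_kernel(
        counts, alpha, beta, dt, n_steps, burn_steps, sample_every, seed
    )


def initial_gate_counts(
    ca: float, ip3: float, p: AstroParams, n_channels: int | None = None
) -> np.ndarray:
    """Deterministic near-stationary initial gate counts (largest remainder)."""
    n = p.N if n_channels is None else n_channels
    pmf = gate_stationary_pmf(ca, ip3, p)
    exact = pmf * n
    counts = np.floor(exact).astype(np.int64)
    rem = exact - counts
    for _ in range(int(n - counts.sum())):
        i = int(np.argmax(rem))
        counts[i] += 1
        rem[i] = -1
    return counts


# ---------------------------------------------------------------------------
# Diffusion operator
# ---------------------------------------------------------------------------


def diffusion_fluxes(
    graph: CompartmentGraph,
    conc: dict[str, float] | np.ndarray,
    species: str,
    p: AstroParams,
) -> np.ndarray:
    """Per-compartment diffusive flux (uM/s), ordered as graph.compartments.

    Flux into i is sum_j D_{i<-j} (c_j - c_i).  Because
    D_{i<-j} V_i = D_{j<-i} V_j for every edge, the operator conserves the
    total amount sum_i V_i c_i exactly.
    """
    d = {"ca": p.d_ca, "ip3": p.d_ip3}[species]
    ids = graph.ids
    if isinstance(conc, dict):
        c = np.array([conc[i] for i in ids])
    else:
        c = np.asarray(conc, dtype=float)
    flux = np.zeros(len(ids))
    for (i, j) in graph.edges:
        ii, jj = graph.index(i), graph.index(j)
        dij = graph.coupling_coefficient(i, j, d)
        dji = graph.coupling_coefficient(j, i, d)
        flux[ii] += dij * (c[jj] - c[ii])
        flux[jj] += dji * (c[ii] - c[jj])
    return flux


def _csr_coupling(graph: CompartmentGraph, p: AstroParams):
    """Directional coupling coefficients in CSR layout over compartments."""
    ids = graph.ids
    nc = len(ids)
    adj: list[list[tuple[int, float, float]]] = [[] for _ in range(nc)]
    for (i, j) in graph.edges:
        ii, jj = graph.index(i), graph.index(j)
        adj[ii].append((jj, graph.coupling_coefficient(i, j, p.d_ca),
                        graph.coupling_coefficient(i, j, p.d_ip3)))
        adj[jj].append((ii, graph.coupling_coefficient(j, i, p.d_ca),
                        graph.coupling_coefficient(j, i, p.d_ip3)))
    indptr = np.zeros(nc + 1, dtype=np.int64)
    indices, cca, cip = [], [], []
    for i in range(nc):
        for (j, a, b) in adj[i]:
            indices.append(j)
            cca.append(a)
            cip.append(b)
        indptr[i + 1] = len(indices)
    return (
        indptr,
        np.array(indices, dtype=np.int64),
        np.array(cca),
        np.array(cip),
    )


# ---------------------------------------------------------------------------
# Simulator
# ---------------------------------------------------------------------------

_CA0 = 0.1  # initial cytosolic Ca2+ [uM]


def simulate_astro(
    graph: CompartmentGraph,
    params: AstroParams | None = None,
    duration: float = 140.0,
    dt: float = 1e-3,
    seed: int = 0,
    trials: int = 1,
    burn_in: float = 20.0,
    sample_every: int = 10,
    deterministic: bool = False,
    glutamate: float | dict[str, float] | None = None,
) -> TraceSet:
    """Simulate the microdomain; returns a seeded multi-trial TraceSet.

    ``duration`` is the total simulated time; the leading ``burn_in``
    seconds are kept in the record but flagged for analysis to discard.
    ``deterministic=True`` replaces the node Markov clusters by their
    expected-value gating (a continuous per-gate open probability, open
    fraction q^3) and switches off the parent Wiener noise — the
    classical deterministic limit of the model.
    """
    p = params if params is not None else AstroParams.calibrated()
    if dt <= 0:
        raise InvalidStepError(f"dt must be positive, got {dt}")
    if duration <= burn_in:
        raise ValueError("duration must exceed the burn-in period")
    graph.validate()

    ids = graph.ids
    nc = len(ids)
    kind = np.array(
        [{Kind.NODE: 0, Kind.SHAFT: 1, Kind.PARENT: 2}[c.kind] for c in graph.compartments],
        dtype=np.int64,
    )
    node_ids = graph.node_ids
    node_ord = np.full(nc, -1, dtype=np.int64)
    for k, nid in enumerate(node_ids):
        node_ord[graph.index(nid)] = k
    nn = len(node_ids)

    indptr, indices, cca, cip = _csr_coupling(graph, p)
    P = _kernels.pack_astro(p)

    glut = np.full(nc, p.g, dtype=float)
    if isinstance(glutamate, dict):
        for cid, val in glutamate.items():
            glut[graph.index(cid)] = val
    elif glutamate is not None:
        glut[:] = float(glutamate)
    glut03 = np.where(glut > 0, glut, 0.0) ** 0.3

    n_steps = int(round(duration / dt))
    nsamp = n_steps // sample_every + 1
    time = np.arange(nsamp) * (dt * sample_every)

    ca_all = np.empty((trials, nsamp, nc))
    ip3_all = np.empty((trials, nsamp, nc))
    nopen_all = np.empty((trials, nsamp, nn))
    clip_fracs = []

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(trials)
    q0 = gate_rates(_CA0, p.ip3_star, p)
    q_open = q0[0] / (q0[0] + q0[1])

    for t in range(trials):
        ca = np.full(nc, _CA0)
        ip3 = np.full(nc, p.ip3_star)
        gates = np.tile(initial_gate_counts(_CA0, p.ip3_star, p), (max(nn, 1), 1))
        q = np.full(max(nn, 1), q_open)
        aux = np.array([q_open, (p.c0 - _CA0) / p.c1])  # parent h, ca_er
        kseed = int(children[t].generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
        ca_out = np.empty((nsamp, nc))
        ip3_out = np.empty((nsamp, nc))
        nopen_out = np.empty((nsamp, max(nn, 1)))
        status, comp, step, clips = _kernels.astro_kernel(
            n_steps, dt, sample_every,
            kind, node_ord, indptr, indices, cca, cip, glut03,
            P, 1 if deterministic else 0, kseed,
            ca, ip3, gates, q, aux,
            ca_out, ip3_out, nopen_out,
        )
        if status != 0:
            raise IntegrationError(ids[int(comp)], float(step) * dt)
        ca_all[t] = ca_out
        ip3_all[t] = ip3_out
        nopen_all[t] = nopen_out[:, :nn]
        clip_fracs.append(clips / (2.0 * n_steps * nc))

    clip_fraction = float(max(clip_fracs)) if clip_fracs else 0.0
    if clip_fraction > CLIP_FRACTION_LIMIT:
        warnings.warn(
            f"negative-concentration clips in {clip_fraction:.2%} of steps "
            f"(limit {CLIP_FRACTION_LIMIT:.2%}); decrease dt",
            RuntimeWarning,
        )

    return TraceSet(
        time=time,
        data={"ca": ca_all, "ip3": ip3_all, "n_open": nopen_all},
        columns={"ca": ids, "ip3": ids, "n_open": node_ids},
        meta={
            "seed": seed,
            "dt": dt,
            "duration": duration,
            "burn_in": burn_in,
            "sample_every": sample_every,
            "trials": trials,
            "deterministic": deterministic,
            "clip_fraction": clip_fraction,
            "geometry": graph.geometry.__dict__.copy(),
        },
    )


# ---------------------------------------------------------------------------
# Deterministic-limit right-hand side (for external ODE oracles)
# ---------------------------------------------------------------------------


def astro_ode_rhs(t, y, graph: CompartmentGraph, p: AstroParams, glut: np.ndarray):
    """RHS of the deterministic limit as a flat ODE system.

    State layout: [ca(nc), ip3(nc), q(nn), h_par, ca_er_par].  Built from
    the scalar reference fluxes, independent of the compiled kernel; used
    to cross-check the Euler-Maruyama path in its sigma_h=0,
    expected-value-gating limit.
    """
    ids = graph.ids
    nc = len(ids)
    node_ids = graph.node_ids
    nn = len(node_ids)
    ca = y[:nc]
    ip3 = y[nc : 2 * nc]
    q = y[2 * nc : 2 * nc + nn]
    h_par, ca_er_par = y[-2], y[-1]
    jd_ca = diffusion_fluxes(graph, ca, "ca", p)
    jd_ip = diffusion_fluxes(graph, ip3, "ip3", p)
    dca = np.zeros(nc)
    dip = np.zeros(nc)
    dq = np.zeros(nn)
    d_h = d_caer = 0.0
    for i, comp in enumerate(graph.compartments):
        if comp.kind is Kind.SHAFT:
            dca[i] = jd_ca[i]
            dip[i] = jd_ip[i]
        elif comp.kind is Kind.NODE:
            k = node_ids.index(comp.id)
            # expected-value gating: open fraction q^3 out of N channels
            n_open_eff = q[k] ** 3 * p.N
            dca[i] = node_ca_rhs(ca[i], ip3[i], n_open_eff, p, jd_ca[i])
            dip[i] = node_ip3_rhs(ca[i], ip3[i], p, glut[i], jd_ip[i])
            alpha, beta = gate_rates(ca[i], ip3[i], p)
            dq[k] = alpha * (1 - q[k]) - beta * q[k]
        else:
            dca[i], d_caer, dip[i], d_h = parent_rhs(
                ca[i], ca_er_par, ip3[i], h_par, p, jd_ca[i], jd_ip[i], glut[i]
            )
    return np.concatenate([dca, dip, dq, [d_h, d_caer]])
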