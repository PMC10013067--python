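"""Unit and property tests for the microdomain Ca2+/IP3 dynamics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp
from scipy.linalg import null_space
from scipy.stats import chisquare

from astroca import (
    AstroParams,
    Geometry,
    InvalidStepError,
    build_chain_model,
    simulate_astro,
)
from astroca.astro_model import (
    _CA0,
    astro_ode_rhs,
    diffusion_fluxes,
    gate_rates,
    gate_stationary_pmf,
    initial_gate_counts,
    markov_gate_step,
    node_ca_rhs,
    node_ip3_rhs,
    parent_rhs,
    simulate_gate_chain,
)


class TestFluxTerms:
    def test_gate_rates_worked_example(self, params):
        alpha, beta = gate_rates(ca=0.1, ip3=0.16, p=params)
        assert alpha == pytest.approx(0.05514, rel=1e-3)
        assert beta == pytest.approx(0.02, rel=1e-12)

    def test_closed_channels_at_er_equilibrium(self, params):
        # ca chosen so that (c0 - ca)/c1 == ca: channel and leak both vanish
        ca_eq = params.c0 / (1 + params.c1)
        serca = params.v3 * ca_eq**2 / (ca_eq**2 + params.k3_node**2)
        rhs = node_ca_rhs(ca_eq, 0.16, 0, params)
        assert rhs == pytest.approx(-serca, rel=1e-12)

    def test_serca_half_max_at_dissociation_constant(self, params):
        # node: subtracting the leak contribution leaves -v3/2
        ca = params.k3_node
        leak = params.v2 * ((params.c0 - ca) / params.c1 - ca)
        assert node_ca_rhs(ca, 0.16, 0, params) == pytest.approx(
            leak - params.v3 / 2, rel=1e-12
        )

    def test_channel_flux_worked_example(self, params):
        # fully open cluster at ca = d5, ip3 = ip3_star
        ca, ip3 = params.d5, 0.16
        base = node_ca_rhs(ca, ip3, 0, params)
        full = node_ca_rhs(ca, ip3, params.N, params)
        assert full - base == pytest.approx(1.2953, rel=1e-3)

    def test_plc_beta_zero_and_worked_example(self, params):
        rhs0 = node_ip3_rhs(0.0, 0.16, params, glut=0.0)
        rhs1 = node_ip3_rhs(0.0, 0.16, params, glut=1.0)
        assert rhs1 - rhs0 == pytest.approx(0.032154, rel=1e-3)

    def test_plc_delta_at_zero_calcium(self, params):
        # ca=0: J_PLCdelta = v4*(1-alpha) = 0.4 uM/s
        rhs = node_ip3_rhs(0.0, params.ip3_star, params, glut=0.0)
        assert rhs == pytest.approx(params.v4 * (1 - params.alpha), rel=1e-12)

    def test_parent_closed_channels(self, params):
        ca, ca_er, ip3 = 0.1, 10.0, 0.3
        d_ca, d_er, _, _ = parent_rhs(ca, ca_er, ip3, h=0.0, p=params)
        leak = params.v2 * (ca_er - ca)
        serca = params.v3 * ca**2 / (ca**2 + params.k3_parent**2)
        assert d_ca == pytest.approx(
            leak - serca + params.v5 - params.k1 * ca, rel=1e-12
        )
        # ER mirrors the cytosolic exchange scaled by the volume ratio
        assert d_er == pytest.approx(-(leak - serca) / params.c1, rel=1e-12)

    def test_parent_serca_half_max(self, params):
        ca = params.k3_parent
        serca = params.v3 * ca**2 / (ca**2 + params.k3_parent**2)
        assert serca == pytest.approx(1.1, rel=1e-12)


class TestGateChain:
    def test_invalid_step(self, params, rng):
        with pytest.raises(InvalidStepError):
            markov_gate_step(np.array([20, 0, 0, 0]), 0.1, 0.16, 0.0, params, rng)

    def test_vanishing_step_freezes_state(self, params, rng):
        counts = initial_gate_counts(0.1, 0.16, params)
        out = counts
        for _ in range(200):
            out = markov_gate_step(out, 0.1, 0.16, 1e-12, params, rng)
        assert np.array_equal(out, counts)

    @given(st.integers(0, 2**31 - 1))
    def test_channel_count_conserved(self, params, seed):
        rng = np.random.default_rng(seed)
        counts = initial_gate_counts(0.1, 0.16, params)
        for _ in range(50):
            counts = markov_gate_step(counts, 0.3, 0.5, 0.05, params, rng)
            assert counts.sum() == params.N
            assert (counts >= 0).all()

    def test_stationary_law_matrix_oracle_and_chisquare(self, params):
        """Clamped chain relaxes to the Binomial(3, p_open) law.

        Cross-checked two ways: the closed form against the null space of
        the exact 4-state generator, and the simulated occupancy against
        both via a chi-square test on 1e5 pooled samples.
        """
        ca, ip3 = 0.15, 0.3
        alpha, beta = gate_rates(ca, ip3, params)
        pmf = gate_stationary_pmf(ca, ip3, params)
        q_gen = np.zeros((4, 4))
        for i in range(4):
            if i < 3:
                q_gen[i, i + 1] = (3 - i) * alpha
            if i > 0:
                q_gen[i, i - 1] = i * beta
            q_gen[i, i] = -q_gen[i].sum()
        stat_dist = null_space(q_gen.T).ravel()
        stat_dist /= stat_dist.sum()
        assert np.abs(stat_dist - pmf).max() < 1e-12

        dt = 1e-3 / max(3 * alpha, 3 * beta)
        spacing = int(3 / ((alpha + beta) * dt))
        counts = simulate_gate_chain(
            ca, ip3, params, n_channels=1000, dt=dt,
            n_steps=spacing * 101, seed=5, burn_steps=spacing,
            sample_every=spacing,
        )
        occ = counts.sum(axis=0)
        assert occ.sum() == 100_000
        _, pval = chisquare(occ, pmf * occ.sum())
        assert pval > 0.01
        # mean open-channel fraction matches (alpha/(alpha+beta))^3
        p_open = (alpha / (alpha + beta)) ** 3
        assert counts[:, 3].mean() / 1000 == pytest.approx(p_open, rel=0.05)


class TestDiffusion:
    def test_uniform_state_is_equilibrium(self, chain15, cal_params):
        flux = diffusion_fluxes(chain15, np.full(len(chain15.ids), 0.37), "ca", cal_params)
        assert np.abs(flux).max() < 1e-14

    def test_two_identical_compartments_antisymmetric(self, cal_params):
        g = build_chain_model(2)
        c = {i: 0.0 for i in g.ids}
        c["n1"], c["n2"] = 1.0, 0.0
        flux = diffusion_fluxes(g, c, "ca", cal_params)
        i1 = g.index("n1")
        assert flux[i1] < 0
        # n1 drains into both of its (empty) neighboring shafts
        expected = -sum(
            g.coupling_coefficient("n1", j, cal_params.d_ca)
            for j in g.neighbors("n1")
        )
        assert flux[i1] == pytest.approx(expected, rel=1e-12)

    @given(st.integers(0, 10_000))
    def test_mass_conservation(self, chain15, cal_params, seed):
        rng = np.random.default_rng(seed)
        c = rng.uniform(0.01, 2.0, len(chain15.ids))
        vols = np.array([comp.volume for comp in chain15.compartments])
        for species in ("ca", "ip3"):
            flux = diffusion_fluxes(chain15, c, species, cal_params)
            total = float(vols @ flux)
            scale = float(np.abs(vols * flux).sum()) or 1.0
            assert abs(total) / scale < 1e-9


class TestSimulator:
    def test_seed_determinism(self, cal_params):
        g = build_chain_model(3)
        a = simulate_astro(g, cal_params, duration=25, seed=42, trials=2)
        b = simulate_astro(g, cal_params, duration=25, seed=42, trials=2)
        assert a == b
        c = simulate_astro(g, cal_params, duration=25, seed=43, trials=2)
        assert not np.array_equal(a.data["ca"], c.data["ca"])

    def test_invalid_dt_and_duration(self, cal_params, chain15):
        with pytest.raises(InvalidStepError):
            simulate_astro(chain15, cal_params, duration=30, dt=0.0)
        with pytest.raises(ValueError):
            simulate_astro(chain15, cal_params, duration=10, burn_in=20)

    def test_state_bounds_and_clip_rate(self, cal_params):
        g = build_chain_model(5)
        ts = simulate_astro(g, cal_params, duration=60, seed=3, trials=2)
        assert (ts.data["ca"] >= 0).all()
        assert (ts.data["ip3"] >= 0).all()
        n_open = ts.data["n_open"]
        assert ((n_open >= 0) & (n_open <= cal_params.N)).all()
        assert ts.meta["clip_fraction"] < 1e-3

    def test_zero_diffusion_decouples_geometry(self, cal_params):
        """With diffusion off, nodes are isolated: shaft geometry is inert
        and shaft concentrations never change."""
        p = cal_params.with_(d_ca=0.0, d_ip3=0.0)
        ts1 = simulate_astro(build_chain_model(3, Geometry(w_shaft=0.2)),
                             p, duration=25, seed=9)
        ts2 = simulate_astro(build_chain_model(3, Geometry(w_shaft=0.4)),
                             p, duration=25, seed=9)
        for n in ("n1", "n2", "n3"):
            assert np.array_equal(ts1.get("ca", n), ts2.get("ca", n))
        shaft = ts1.get("ca", "s_n1_n2")
        assert np.all(shaft == shaft[:, :1])

    def test_deterministic_limit_matches_ode_oracle(self):
        """sigma_h=0 + expected-value gating reduces to the classical ODE
        system; the Euler path must track a high-accuracy integration."""
        p = AstroParams.calibrated(sigma_h=0.0)
        g = build_chain_model(3)
        ts = simulate_astro(
            g, p, duration=10, dt=2e-4, seed=0, trials=1, burn_in=0,
            deterministic=True, sample_every=50,
        )
        nc, nn = len(g.ids), len(g.node_ids)
        alpha, beta = gate_rates(_CA0, p.ip3_star, p)
        q0 = alpha / (alpha + beta)
        y0 = np.concatenate(
            [np.full(nc, _CA0), np.full(nc, p.ip3_star), np.full(nn, q0),
             [q0, (p.c0 - _CA0) / p.c1]]
        )
        sol = solve_ivp(
            astro_ode_rhs, (0, 10), y0, args=(g, p, np.full(nc, p.g)),
            t_eval=ts.time, rtol=1e-10, atol=1e-12, method="LSODA",
        )
        assert np.abs(ts.data["ca"][0] - sol.y[:nc].T).max() < 1e-3

    def test_step_size_robustness(self, cal_params):
        """Halving dt moves trial-averaged peak counts by less than the
        across-trial spread."""
        from astroca.analysis import peak_table

        g = build_chain_model(5)
        stats = {}
        for dt in (1e-3, 5e-4):
            ts = simulate_astro(g, cal_params, duration=80, dt=dt, seed=17, trials=4)
            per = peak_table(ts)
            per = per[per["compartment"].str.startswith("n")]
            by_trial = per.groupby("trial")["n_peaks"].mean()
            stats[dt] = (by_trial.mean(), by_trial.std())
        diff = abs(stats[1e-3][0] - stats[5e-4][0])
        assert diff < max(stats[1e-3][1], stats[5e-4][1])
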