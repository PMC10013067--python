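"""Unit tests for the tripartite synapse components and simulator."""

import math

import numpy as np
import pytest
from scipy.linalg import null_space
from scipy.stats import chisquare

from astroca import AstroParams, Geometry, SynapseParams, simulate_tripartite
from astroca.synapse_model import (
    astro_release_step,
    cleft_glutamate_step,
    hh_rates,
    hh_resting_state,
    mg_block,
    postsyn_step,
    presyn_ca_step,
    presyn_membrane_step,
    release_chain_step,
    sensor_transition_rates,
    spontaneous_rate,
    vesicle_pools_step,
)
from astroca._kernels import sensor_chain_kernel


@pytest.fixture(scope="module")
def sp():
    return SynapseParams()


class TestMembrane:
    def test_rest_is_stable_without_input(self, sp):
        v = -65.0
        m, n, h = hh_resting_state(sp, v)
        dt = 1e-5
        for _ in range(100_000):  # 1 s
            v, m, n, h = presyn_membrane_step(v, m, n, h, sp, dt, i_app=0.0)
        assert abs(v + 65.0) < 1.0

    def test_constant_current_gives_periodic_spiking(self, sp):
        def count_spikes(t_total):
            v = -65.0
            m, n, h = hh_resting_state(sp, v)
            dt = 1e-5
            crossings = 0
            prev = v
            for _ in range(int(t_total / dt)):
                v, m, n, h = presyn_membrane_step(v, m, n, h, sp, dt, i_app=10.0)
                if prev < 0.0 <= v:
                    crossings += 1
                prev = v
                assert 0.0 <= m <= 1.0 and 0.0 <= n <= 1.0 and 0.0 <= h <= 1.0
            return crossings

        one = count_spikes(1.0)
        two = count_spikes(2.0)
        assert one > 30  # suprathreshold tonic firing
        assert two == pytest.approx(2 * one, abs=2)

    def test_rate_functions_finite_at_singular_points(self):
        for v in (-40.0, -55.0):
            assert all(np.isfinite(hh_rates(v)))


class TestPresynCalcium:
    def test_zero_glutamate_relaxes_ip3_to_steady_state(self, sp, params):
        ip3 = 1.0
        for _ in range(60_000):  # 120 s at the 0.14 1/s loss rate
            _, _, _, _, ip3, _ = presyn_ca_step(
                -65.0, 0.0, 0.1, 0.1, 10.0, ip3, 0.7, 0.0, sp, params, 2e-3
            )
        assert ip3 == pytest.approx(params.ip3_star, rel=1e-3)

    def test_pump_half_max(self, sp, params):
        # with the VGCC gate shut, the Ca2+ balance at ca = k_pmca is
        # leak minus half the maximal pump flux
        ca = sp.k_pmca
        dt = 1e-6
        _, ca2, *_ = presyn_ca_step(-100.0, 0.0, ca, 0.1, 10.0, 0.16, 0.7,
                                    0.0, sp, params, dt)
        leak = sp.v_leak_pre * (sp.ca_out - ca)
        assert (ca2 - ca) / dt == pytest.approx(leak - sp.v_pmca / 2, rel=1e-9)

    def test_er_exchange_conserved(self, sp, params, rng):
        ca_slow, ca_er = 0.1, 10.0
        m_ca, ip3, h = 0.0, 0.3, 0.7
        for _ in range(5000):
            v = rng.uniform(-80, 40)
            m_ca, _, ca_slow2, ca_er2, ip3, h = presyn_ca_step(
                v, m_ca, 0.1, ca_slow, ca_er, ip3, h, rng.uniform(0, 5),
                sp, params, 1e-4
            )
            # ER loses exactly what the cytosolic slow pool gains
            assert ca_er2 - ca_er == pytest.approx(
                -(ca_slow2 - ca_slow) / params.c1, rel=1e-9, abs=1e-12
            )
            ca_slow, ca_er = ca_slow2, ca_er2


class TestReleaseChain:
    def test_zero_calcium_drains_to_empty_sensor(self, sp, rng):
        state = 4
        for _ in range(5000):
            state, fired = release_chain_step(state, 0.0, sp, 1e-4, rng)
            assert not fired
        assert state == 0

    def test_spontaneous_rate_sigmoid(self, sp):
        cas = np.linspace(0, 20, 200)
        lam = np.array([spontaneous_rate(c, sp) for c in cas])
        assert (np.diff(lam) >= 0).all()
        assert lam.max() <= sp.a3 * sp.release_scale
        assert spontaneous_rate(1e9, sp) == pytest.approx(sp.a3)

    def test_stationary_law_vs_generator_oracle(self, sp):
        """Clamped-Ca sensor occupancy matches the exact 7-state chain."""
        ca = 10.0
        q = np.zeros((7, 7))
        for s in range(7):
            f, b = sensor_transition_rates(s, ca, sp)
            if s < 6:
                q[s, s + 1] = f
            if s > 0:
                q[s, s - 1] = b
            q[s, s] = -q[s].sum()
        pi = null_space(q.T).ravel()
        pi /= pi.sum()

        rates = np.array([sensor_transition_rates(s, ca, sp) for s in range(7)])
        dt = 2e-3 / rates.max()
        pf = 1.0 - np.exp(-rates[:, 0] * dt)
        pb = 1.0 - np.exp(-rates[:, 1] * dt)
        relax_steps = int(1.0 / rates[rates > 0].min() / dt)
        spacing = 3 * relax_steps
        occ = sensor_chain_kernel(
            1000, 0, pf, pb, spacing * 101, spacing, spacing, 77
        )
        assert occ.sum() == 100_000
        _, pval = chisquare(occ, pi * occ.sum())
        assert pval > 0.01


class TestPoolsAndCleft:
    def test_recovery_without_release(self, sp):
        r, e = 0.2, 0.0
        for _ in range(200_000):
            r, e, i = vesicle_pools_step(r, e, 0.0, sp, 1e-4)
        assert r == pytest.approx(1.0, abs=1e-3)

    def test_unit_release_rate_first_order(self, sp):
        dt = 1e-4
        r, e, i = vesicle_pools_step(1.0, 0.0, 1.0, sp, dt)
        assert e == pytest.approx(dt, rel=1e-3)

    def test_simplex_conserved_under_random_driving(self, sp, rng):
        r, e = 1.0, 0.0
        for _ in range(100_000):
            f_r = rng.choice([0.0, 0.0, 0.0, 1.0, 2.0]) / 1e-4
            r, e, i = vesicle_pools_step(r, e, f_r * rng.random(), sp, 1e-4)
            assert abs(r + e + i - 1.0) < 1e-9
            assert r >= 0 and e >= -1e-12

    def test_cleft_clearance_only_decay(self, sp):
        g, dt = 50.0, 1e-5
        g2 = cleft_glutamate_step(g, 0.0, sp, dt)
        assert (g - g2) / dt == pytest.approx(sp.r_cleft * g, rel=1e-9)

    def test_cleft_steady_state(self, sp):
        e = 0.05
        g = 0.0
        for _ in range(20_000):
            g = cleft_glutamate_step(g, e, sp, 1e-4)
        assert g == pytest.approx(sp.n_v * sp.g_v * e / sp.r_cleft, rel=1e-4)

    def test_cleft_frozen_without_source_or_clearance(self):
        p = SynapseParams(r_cleft=0.0)
        assert cleft_glutamate_step(3.0, 0.0, p, 1e-3) == 3.0


class TestAstroRelease:
    def test_gates_close_at_zero_calcium(self, sp):
        o, r, e, g = (0.5, 0.5, 0.5), 0.5, 0.1, 1.0
        for _ in range(100_000):  # 20 s; slowest gate closes at 0.4 1/s
            o, r, e, g = astro_release_step(o, r, e, g, 0.0, sp, 2e-4)
        assert max(o) < 1e-3
        assert g < 1e-3

    def test_threshold_blocks_release(self, sp):
        # gates open but Ca below threshold: the pool only recovers
        ca = sp.ca_ast_th * 0.9
        o, r, e, g = (0.9, 0.9, 0.9), 0.5, 0.0, 0.0
        r_prev = r
        for _ in range(1000):
            o, r, e, g = astro_release_step(o, r, e, g, ca, sp, 1e-4)
            assert r >= r_prev - 1e-12
            r_prev = r

    def test_gate_steady_state_closed_form(self, sp):
        ca = 0.5
        o, r, e, g = (0.0, 0.0, 0.0), 1.0, 0.0, 0.0
        for _ in range(400_000):
            o, r, e, g = astro_release_step(o, r, e, g, ca, sp, 1e-4)
        for oj, kp, km in zip(o, (sp.k1_plus, sp.k2_plus, sp.k3_plus),
                              (sp.k1_minus, sp.k2_minus, sp.k3_minus)):
            assert oj == pytest.approx(kp * ca / (kp * ca + km), rel=1e-9)


class TestPostsyn:
    def test_rest_without_glutamate(self, sp):
        v, ma, mn, c = sp.v_post_rest, 0.0, 0.0, sp.c_post_rest
        for _ in range(10_000):
            v, ma, mn, c = postsyn_step(v, ma, mn, c, 0.0, sp, 1e-4)
        assert v == sp.v_post_rest
        assert c == sp.c_post_rest

    def test_mg_block_worked_example_and_monotonicity(self, sp):
        assert mg_block(0.0, sp) == pytest.approx(0.781, rel=1e-3)
        vs = np.linspace(-90, 40, 100)
        blocks = np.array([mg_block(v, sp) for v in vs])
        assert ((blocks > 0) & (blocks < 1)).all()
        assert (np.diff(blocks) > 0).all()

    def test_receptor_gate_steady_states(self, sp):
        g = 50.0
        v, ma, mn, c = sp.v_post_rest, 0.0, 0.0, sp.c_post_rest
        for _ in range(600_000):
            v, ma, mn, c = postsyn_step(v, ma, mn, c, g, sp, 1e-5)
        assert ma == pytest.approx(
            sp.alpha_ampa * g / (sp.alpha_ampa * g + sp.beta_ampa), rel=1e-9
        )
        assert mn == pytest.approx(
            sp.alpha_nmda * g / (sp.alpha_nmda * g + sp.beta_nmda), rel=1e-6
        )


class TestTripartiteSimulator:
    def test_seed_determinism(self):
        a = simulate_tripartite(duration=3, seed=5, trials=2)
        b = simulate_tripartite(duration=3, seed=5, trials=2)
        assert a == b

    def test_pool_invariants_and_finite_traces(self):
        ts = simulate_tripartite(duration=6, seed=8, trials=2)
        r, e = ts.get("R", "R"), ts.get("E", "E")
        assert (r >= 0).all() and (e >= -1e-12).all()
        assert (r + e <= 1 + 1e-9).all()
        for name in ts.data:
            assert np.isfinite(ts.data[name]).all()
        n_open = ts.get("n_open", "n_open")
        assert ((n_open >= 0) & (n_open <= 20)).all()

    def test_severed_feedback_keeps_slow_pool_at_baseline(self):
        on = simulate_tripartite(duration=12, seed=6, trials=2)
        off = simulate_tripartite(duration=12, seed=6, trials=2,
                                  astro_feedback=False)
        slow_on = on.window().get("ca_slow", "ca_slow").mean()
        slow_off = off.window().get("ca_slow", "ca_slow").mean()
        assert slow_off < 0.3  # near the ~0.1 uM resting level
        assert slow_on > slow_off + 0.2

    def test_atrophic_node_releases_less_glutamate(self):
        ctrl = simulate_tripartite(duration=12, seed=6, trials=3)
        atro = simulate_tripartite(duration=12, seed=6, trials=3,
                                   astro_geom=Geometry(w_node=0.2))
        g_ctrl = ctrl.window().get("g_ast", "g_ast").mean()
        g_atro = atro.window().get("g_ast", "g_ast").mean()
        assert g_atro < g_ctrl
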