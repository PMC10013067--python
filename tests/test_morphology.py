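import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from astroca import (
    Geometry,
    InvalidGeometryError,
    InvalidTopologyError,
    MissingEdgeError,
    Kind,
    build_chain_model,
    build_mesh_model,
    build_star_model,
    chain_links,
    compartment_volume,
    mesh30_links,
)

widths = st.floats(0.05, 2.0)
lengths = st.floats(0.2, 8.0)


def geom_strategy():
    return st.builds(
        lambda a, b, l, wp, lp: Geometry(
            w_node=max(a, b), w_shaft=min(a, b), l_shaft=l, w_parent=wp, l_parent=lp
        ),
        widths, widths, lengths, widths, lengths,
    )


class TestVolumes:
    def test_sphere_and_cylinder_closed_forms(self):
        g = Geometry(w_node=0.4, w_shaft=0.2, l_shaft=1.0)
        assert compartment_volume("node", g) == pytest.approx(0.03351, rel=1e-3)
        assert compartment_volume("shaft", g) == pytest.approx(0.03142, rel=1e-3)

    @given(geom_strategy())
    def test_volume_formulas_exact(self, g):
        assert compartment_volume(Kind.NODE, g) == pytest.approx(
            math.pi / 6 * g.w_node**3, rel=1e-12
        )
        assert compartment_volume(Kind.SHAFT, g) == pytest.approx(
            math.pi / 4 * g.w_shaft**2 * g.l_shaft, rel=1e-12
        )
        assert compartment_volume(Kind.PARENT, g) == pytest.approx(
            math.pi / 4 * g.w_parent**2 * g.l_parent, rel=1e-12
        )

    @pytest.mark.parametrize("field", ["w_node", "w_shaft", "l_shaft", "w_parent"])
    def test_degenerate_geometry_rejected(self, field):
        with pytest.raises(InvalidGeometryError):
            Geometry(**{field: 0.0})

    def test_node_narrower_than_shaft_rejected(self):
        with pytest.raises(InvalidGeometryError):
            Geometry(w_node=0.1, w_shaft=0.2)


class TestCoupling:
    def test_worked_example(self):
        # node of width 0.4 um coupled through a 0.2 um shaft of length 1 um
        g = build_chain_model(1, Geometry(w_node=0.4, w_shaft=0.2, l_shaft=1.0))
        d = g.coupling_coefficient("n1", "s_n1_parent", 0.1)
        assert d == pytest.approx(0.1340, rel=1e-3)

    def test_zero_diffusion_constant(self, chain15):
        assert chain15.coupling_coefficient("n1", "s_n1_n2", 0.0) == 0.0

    def test_symmetric_for_identical_compartments(self):
        g = build_chain_model(2)
        # two nodes seen from the same shaft have equal volumes
        d1 = g.coupling_coefficient("n1", "s_n1_n2", 1.0)
        d2 = g.coupling_coefficient("n2", "s_n1_n2", 1.0)
        assert d1 == d2

    def test_missing_edge(self, chain15):
        with pytest.raises(MissingEdgeError):
            chain15.coupling_coefficient("n1", "n3", 1.0)

    @given(geom_strategy(), st.floats(0.01, 100.0))
    def test_scaling_and_detailed_balance(self, geom, diff):
        g = build_chain_model(3, geom)
        for (i, j) in g.edges:
            dij = g.coupling_coefficient(i, j, diff)
            # linear in the diffusion constant
            assert g.coupling_coefficient(i, j, 2 * diff) == pytest.approx(
                2 * dij, rel=1e-12
            )
            # volume-weighted symmetry makes the operator mass-conserving
            dji = g.coupling_coefficient(j, i, diff)
            assert dij * g[i].volume == pytest.approx(dji * g[j].volume, rel=1e-12)


class TestBuilders:
    def test_minimal_chain(self):
        g = build_chain_model(1)
        kinds = [c.kind for c in g.compartments]
        assert kinds.count(Kind.NODE) == 1
        assert kinds.count(Kind.SHAFT) == 1
        assert kinds.count(Kind.PARENT) == 1
        assert len(g.edges) == 2

    def test_chain15_fixture_counts(self, chain15):
        assert len(chain15.node_ids) == 15
        assert len(chain15.of_kind(Kind.SHAFT)) == 16  # 14 internal + 2 terminal
        assert len(chain15.of_kind(Kind.PARENT)) == 1

    @pytest.mark.parametrize("n", [1, 2, 5, 15, 30])
    def test_chain_connected(self, n):
        g = build_chain_model(n)
        assert nx.is_connected(g.to_networkx())

    def test_star(self):
        g = build_star_model(3)
        assert len(g.node_ids) == 3
        assert len(g.of_kind(Kind.SHAFT)) == 3
        assert g.degree("parent") == 3
        assert all(g.degree(n) == 1 for n in g.node_ids)

    def test_star_minimal_is_path(self):
        g = build_star_model(1)
        assert sorted(c.kind.value for c in g.compartments) == [
            "node", "parent", "shaft",
        ]

    def test_shafts_have_no_er(self, chain15):
        for c in chain15.compartments:
            assert c.has_er == (c.kind in (Kind.NODE, Kind.PARENT))

    def test_mesh30_branch_degrees(self):
        g15 = build_chain_model(15)
        g30 = build_mesh_model(mesh30_links())
        assert len(g30.node_ids) == 30
        for branch in ("n5", "n8", "n12"):
            assert g30.degree(branch) > g15.degree(branch)
        for unchanged in ("n1", "n6", "n10"):
            assert g30.degree(unchanged) == g15.degree(unchanged)

    def test_mesh_from_spec_matches_chain(self):
        a = build_mesh_model(chain_links(15))
        b = build_chain_model(15)
        assert a.ids == b.ids
        assert a.edges == b.edges

    def test_empty_spec_rejected(self):
        with pytest.raises(InvalidTopologyError):
            build_mesh_model({"nodes": [], "links": []})

    def test_disconnected_spec_rejected(self):
        with pytest.raises(InvalidTopologyError):
            build_mesh_model(
                {"nodes": ["a", "b", "c"], "links": [["a", "b"]]}
            )

    def test_unknown_node_in_link_rejected(self):
        with pytest.raises(InvalidTopologyError):
            build_mesh_model({"nodes": ["a"], "links": [["a", "zz"]]})
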