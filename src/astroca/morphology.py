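"""Compartment graphs for astrocytic fine processes.

The spongiform domain of an astrocyte is discretized into three kinds of
compartments: *nodes* (bulbous enlargements, modelled as spheres, carrying
endoplasmic reticulum and hence the stochastic IP3R Ca2+ source), *shafts*
(thin connecting tubes, modelled as cylinders, organelle-free so purely
diffusive) and a single *parent process* (a thick cylinder with its own
Ca2+/IP3 machinery).  This module builds those graphs, validates them, and
computes every geometry-derived quantity that feeds the diffusion operator:
volumes, inter-compartment cross-sections and center distances, and the
per-edge diffusive coupling coefficients

    D_{i<-j} = d * Sc_ij / (V_i * d_ij)        [1/s]

which are deliberately asymmetric between compartments of unequal volume —
the physical reason Ca2+ exchange differs at branch points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import networkx as nx

from .errors import InvalidGeometryError, InvalidTopologyError, MissingEdgeError

__all__ = [
    "Kind",
    "Geometry",
    "Compartment",
    "CompartmentGraph",
    "MorphologySpec",
    "compartment_volume",
    "build_chain_model",
    "build_star_model",
    "build_mesh_model",
    "chain_links",
    "mesh30_links",
    "star_links",
    "CONTROL_GEOMETRY",
]

PARENT_ID = "parent"


class Kind(str, Enum):
    NODE = "node"
    SHAFT = "shaft"
    PARENT = "parent"


@dataclass(frozen=True)
class Geometry:
    """Microdomain geometry in micrometres.

    ``w_node`` is the node diameter, ``w_shaft``/``l_shaft`` the shaft
    diameter and length, ``w_parent``/``l_parent`` the parent-process
    cylinder.  The model constrains ``w_node >= w_shaft``.
    """

    w_node: float = 0.4
    w_shaft: float = 0.2
    l_shaft: float = 1.0
    w_parent: float = 1.0
    l_parent: float = 5.0

    def __post_init__(self):
        for name in ("w_node", "w_shaft", "l_shaft", "w_parent", "l_parent"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise InvalidGeometryError(f"{name} must be positive, got {v!r}")
        if self.w_node < self.w_shaft:
            raise InvalidGeometryError(
                f"node width ({self.w_node}) must be >= shaft width ({self.w_shaft})"
            )

    def with_(self, **kwargs) -> "Geometry":
        return replace(self, **kwargs)


#: Control geometry: median node/shaft sizes measured in live tissue,
#: rounded as in the sweep grids (w_node=0.4, w_shaft=0.2, l_shaft=1 um).
CONTROL_GEOMETRY = Geometry()


def compartment_volume(kind: Kind | str, geom: Geometry) -> float:
    """Volume in um^3 of a compartment of the given kind.

    Nodes are spheres of diameter ``w_node``; shafts and the parent process
    are cylinders of the corresponding diameter and length.
    """
    kind = Kind(kind)
    if kind is Kind.NODE:
        return math.pi / 6.0 * geom.w_node**3
    if kind is Kind.SHAFT:
        return math.pi / 4.0 * geom.w_shaft**2 * geom.l_shaft
    return math.pi / 4.0 * geom.w_parent**2 * geom.l_parent


@dataclass(frozen=True)
class Compartment:
    id: str
    kind: Kind
    volume: float

    @property
    def has_er(self) -> bool:
        # Shafts contain no organelles; nodes and the parent carry ER.
        return self.kind in (Kind.NODE, Kind.PARENT)


@dataclass
class CompartmentGraph:
    """Typed compartment graph with per-edge cross-section and distance.

    Edges are stored once per unordered pair; ``coupling_coefficient`` is
    directional (flux *into* ``i`` from ``j``).
    """

    geometry: Geometry
    compartments: list[Compartment] = field(default_factory=list)
    # (i, j) with i < j lexicographically -> (Sc [um^2], d [um])
    edges: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self._index = {c.id: k for k, c in enumerate(self.compartments)}

    # -- construction ---------------------------------------------------

    def add_compartment(self, cid: str, kind: Kind) -> Compartment:
        if cid in self._index:
            raise InvalidTopologyError(f"duplicate compartment id {cid!r}")
        comp = Compartment(cid, kind, compartment_volume(kind, self.geometry))
        self._index[cid] = len(self.compartments)
        self.compartments.append(comp)
        return comp

    def add_edge(self, i: str, j: str, cross_section: float, center_distance: float):
        if cross_section <= 0 or center_distance <= 0:
            raise InvalidGeometryError("edge cross-section and distance must be positive")
        a, b = self[i], self[j]
        allowed = {
            frozenset({Kind.NODE, Kind.SHAFT}),
            frozenset({Kind.SHAFT, Kind.SHAFT}),
            frozenset({Kind.SHAFT, Kind.PARENT}),
            frozenset({Kind.NODE, Kind.PARENT}),
        }
        if frozenset({a.kind, b.kind}) not in allowed:
            raise InvalidTopologyError(f"edge {i}-{j} joins incompatible kinds")
        self.edges[self._key(i, j)] = (cross_section, center_distance)

    @staticmethod
    def _key(i: str, j: str) -> tuple[str, str]:
        return (i, j) if i <= j else (j, i)

    # -- lookup ---------------------------------------------------------

    def __getitem__(self, cid: str) -> Compartment:
        return self.compartments[self._index[cid]]

    def __contains__(self, cid: str) -> bool:
        return cid in self._index

    def index(self, cid: str) -> int:
        return self._index[cid]

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.compartments]

    def of_kind(self, kind: Kind | str) -> list[Compartment]:
        kind = Kind(kind)
        return [c for c in self.compartments if c.kind is kind]

    @property
    def node_ids(self) -> list[str]:
        return [c.id for c in self.of_kind(Kind.NODE)]

    def neighbors(self, cid: str) -> list[str]:
        out = []
        for (a, b) in self.edges:
            if a == cid:
                out.append(b)
            elif b == cid:
                out.append(a)
        return out

    def degree(self, cid: str) -> int:
        return len(self.neighbors(cid))

    def edge_geometry(self, i: str, j: str) -> tuple[float, float]:
        try:
            return self.edges[self._key(i, j)]
        except KeyError:
            raise MissingEdgeError(f"no edge between {i!r} and {j!r}") from None

    def coupling_coefficient(self, i: str, j: str, diff_const: float) -> float:
        """Diffusive rate D_{i<-j} = diff_const * Sc / (V_i * d) in 1/s.

        Asymmetric in i<->j whenever the two volumes differ.
        """
        sc, d = self.edge_geometry(i, j)
        return diff_const * sc / (self[i].volume * d)

    # -- validation -----------------------------------------------------

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for c in self.compartments:
            g.add_node(c.id, kind=c.kind.value, volume=c.volume)
        for (i, j), (sc, d) in self.edges.items():
            g.add_edge(i, j, cross_section=sc, center_distance=d)
        return g

    def validate(self) -> "CompartmentGraph":
        if not self.compartments:
            raise InvalidTopologyError("empty morphology")
        g = self.to_networkx()
        if g.number_of_nodes() > 1 and not nx.is_connected(g):
            raise InvalidTopologyError("compartment graph is not connected")
        parents = self.of_kind(Kind.PARENT)
        if len(parents) != 1:
            raise InvalidTopologyError(f"expected exactly one parent, got {len(parents)}")
        return self


# ---------------------------------------------------------------------------
# Morphology specifications (node-level adjacency; shafts are implicit)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MorphologySpec:
    """Node-level description of a microdomain.

    ``links`` are pairs of node labels, where the label ``"parent"`` denotes
    the parent process.  Every link is realized as one shaft compartment, so
    a node-parent link becomes node-shaft-parent.
    """

    nodes: tuple[str, ...]
    links: tuple[tuple[str, str], ...]

    @staticmethod
    def from_dict(d: dict) -> "MorphologySpec":
        return MorphologySpec(
            nodes=tuple(str(n) for n in d["nodes"]),
            links=tuple((str(a), str(b)) for a, b in d["links"]),
        )

    def to_dict(self) -> dict:
        return {"nodes": list(self.nodes), "links": [list(l) for l in self.links]}


def _node_label(n: int | str) -> str:
    return f"n{n}" if not str(n).startswith(("n", PARENT_ID)) else str(n)


def chain_links(n_nodes: int) -> MorphologySpec:
    """Chain-mesh adjacency: nodes 1..n in a path, terminal shafts to parent.

    This is the versioned 15-node fixture at ``n_nodes=15``: the path closes
    into a mesh loop through the parent process, which both ends attach to.
    """
    if n_nodes < 1:
        raise InvalidTopologyError("need at least one node")
    nodes = tuple(f"n{i}" for i in range(1, n_nodes + 1))
    links = [(f"n{i}", f"n{i+1}") for i in range(1, n_nodes)]
    links.append(("n1", PARENT_ID))
    if n_nodes > 1:
        links.append((f"n{n_nodes}", PARENT_ID))
    return MorphologySpec(nodes, tuple(links))


#: Extra node-node shafts of the 30-node fixture relative to the 15-node
#: fixture.  Nodes n5, n8 and n12 gain connecting shafts (branch points);
#: n1, n6 and n10 keep their original degree.
MESH30_EXTRA = (
    ("n5", "n16"), ("n5", "n17"),
    ("n8", "n18"), ("n8", "n19"),
    ("n12", "n20"),
    ("n16", "n21"), ("n17", "n22"), ("n18", "n23"), ("n19", "n24"),
    ("n20", "n25"), ("n21", "n26"), ("n22", "n27"), ("n23", "n28"),
    ("n24", "n29"), ("n25", "n30"),
)


def mesh30_links() -> MorphologySpec:
    """30-node fixture: the 15-node fixture plus 15 nodes branching at n5/n8/n12."""
    base = chain_links(15)
    nodes = base.nodes + tuple(f"n{i}" for i in range(16, 31))
    return MorphologySpec(nodes, base.links + MESH30_EXTRA)


def star_links(n_nodes: int) -> MorphologySpec:
    """Star adjacency: every node has its own shaft straight to the parent."""
    if n_nodes < 1:
        raise InvalidTopologyError("need at least one node")
    nodes = tuple(f"n{i}" for i in range(1, n_nodes + 1))
    return MorphologySpec(nodes, tuple((n, PARENT_ID) for n in nodes))


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def _realize(spec: MorphologySpec, geom: Geometry) -> CompartmentGraph:
    if not spec.nodes:
        raise InvalidTopologyError("morphology spec lists no nodes")
    if not spec.links:
        raise InvalidTopologyError("morphology spec lists no links")
    graph = CompartmentGraph(geometry=geom)
    for n in spec.nodes:
        graph.add_compartment(n, Kind.NODE)
    graph.add_compartment(PARENT_ID, Kind.PARENT)

    # The narrower aperture -- the shaft cross-section -- is the physical
    # bottleneck for flux at both node-shaft and shaft-parent interfaces.
    sc = math.pi / 4.0 * geom.w_shaft**2
    d_ns = (geom.w_node + geom.l_shaft) / 2.0
    d_sp = (geom.l_shaft + geom.w_parent) / 2.0

    seen = set()
    for a, b in spec.links:
        key = tuple(sorted((a, b)))
        if key in seen:
            raise InvalidTopologyError(f"duplicate link {a}-{b}")
        seen.add(key)
        for end in (a, b):
            if end != PARENT_ID and end not in graph:
                raise InvalidTopologyError(f"link references unknown node {end!r}")
        shaft_id = f"s_{a}_{b}"
        graph.add_compartment(shaft_id, Kind.SHAFT)
        for end in (a, b):
            if end == PARENT_ID:
                graph.add_edge(shaft_id, PARENT_ID, sc, d_sp)
            else:
                graph.add_edge(end, shaft_id, sc, d_ns)
    return graph.validate()


def build_chain_model(n_nodes: int = 15, geom: Geometry | None = None) -> CompartmentGraph:
    """Chain-mesh microdomain: a path of nodes whose ends attach to the parent."""
    return _realize(chain_links(n_nodes), geom or CONTROL_GEOMETRY)


def build_star_model(n_nodes: int, geom: Geometry | None = None) -> CompartmentGraph:
    """Star microdomain: nodes individually shafted to the parent process."""
    return _realize(star_links(n_nodes), geom or CONTROL_GEOMETRY)


def build_mesh_model(
    spec: MorphologySpec | dict | Sequence, geom: Geometry | None = None
) -> CompartmentGraph:
    """Arbitrary node-level mesh given an adjacency description."""
    if isinstance(spec, dict):
        spec = MorphologySpec.from_dict(spec)
    elif not isinstance(spec, MorphologySpec):
        links = tuple((str(a), str(b)) for a, b in spec)
        nodes = sorted({x for l in links for x in l if x != PARENT_ID})
        spec = MorphologySpec(tuple(nodes), links)
    return _realize(spec, geom or CONTROL_GEOMETRY)
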