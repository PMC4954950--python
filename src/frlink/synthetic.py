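"""Fixture graphs and parametric generators with controllable PWCS structure.

Two small fixture graphs reproduce the worked examples used throughout
the documentation and tests: a 5-node introduction scenario in three
variants (0, 1 or 2 common neighbors between introducer and acceptor)
and a 7-node graph on which every directed introduction weight can be
computed by hand.

Two generators stand in for real benchmark networks: Erdos-Renyi graphs
(the no-structure null: P1 ~ P2 ~ P3) and planted-weak-clique networks —
dense blocks sparsely interconnected — whose census lands in the
significant-PWCS regime (P1 > P2 > P3) at default parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from frlink.graph_core import Network

__all__ = [
    "GeneratorSpec",
    "fig4_graph",
    "fig3_graphs",
    "gen_erdos_renyi",
    "gen_planted_weak_clique",
    "non_pwcs_graph",
]

#: Frozen default parameters of the planted-weak-clique benchmark used
#: across the test suite: 12 dense blocks of 8 nodes (intra density 0.9)
#: plus 3 bipartite connector modules with parts of 6 (cross density
#: 0.9), interconnected at probability 0.01.  Chosen once by running the
#: census: the regime is significant-PWCS for every generator seed
#: checked, and the connector modules give the benchmark the spoke-model
#: (hub-complex) structure on which degree-penalizing baselines misrank
#: candidates while tie-strength-aware indices do not.
PLANTED_DEFAULTS = dict(
    n_blocks=12,
    block_size=8,
    intra_p=0.9,
    inter_p=0.01,
    n_connectors=3,
    connector_part=6,
    connector_p=0.9,
)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parametric generator request; identical spec + seed gives an
    identical network."""

    family: str  # "erdos_renyi" | "planted_weak_clique"
    params: dict
    seed: int = 0

    def generate(self) -> Network:
        if self.family == "erdos_renyi":
            return gen_erdos_renyi(seed=self.seed, **self.params)
        if self.family == "planted_weak_clique":
            return gen_planted_weak_clique(seed=self.seed, **self.params)
        raise ValueError(f"unknown generator family {self.family!r}")


def fig4_graph() -> Network:
    """The 7-node worked-example graph.

    Nodes 1 and 2 are non-adjacent with common neighbors 3 and 4;
    Gamma(3) = {1,2,4,5,7}, Gamma(4) = {1,2,3,6}, Gamma(2) = {3,4,7}.
    On it, f_231 = 1/3, f_241 = 1/2, f_132 = 1/2, f_142 = 1/2, so
    f_21 = 5/6, f_12 = 1 and S_FR(1,2) = 11/6.
    """
    return Network(
        [
            ("1", "3"),
            ("1", "4"),
            ("2", "3"),
            ("2", "4"),
            ("2", "7"),
            ("3", "4"),
            ("3", "5"),
            ("3", "7"),
            ("4", "6"),
        ]
    )


def fig3_graphs() -> tuple[Network, Network, Network]:
    """Three 5-node introduction scenarios.

    In each, introducer node 2 (degree 4) is adjacent to nominee 1 and
    acceptor 3; the variants (a), (b), (c) give nodes 2 and 3 exactly
    0, 1 and 2 common neighbors, so f_123 = 1/3, 1/2 and 1.
    """
    base = [("2", "1"), ("2", "3"), ("2", "4"), ("2", "5")]
    a = Network(base)
    b = Network(base + [("3", "4")])
    c = Network(base + [("3", "4"), ("3", "5")])
    return a, b, c


def gen_erdos_renyi(n: int, p: float, seed: int = 0) -> Network:
    """Seeded G(n, p) with string node labels n000, n001, ...

    The census on such graphs is flat: every closure probability is
    about p regardless of tie labels, mirroring degree-preserving null
    networks.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    g = nx.gnp_random_graph(n, p, seed=seed)
    width = len(str(n - 1))
    mapping = {i: f"n{i:0{width}d}" for i in g.nodes}
    return Network.from_networkx(nx.relabel_nodes(g, mapping))


def gen_planted_weak_clique(
    n_blocks: int = 12,
    block_size: int = 8,
    intra_p: float = 0.9,
    inter_p: float = 0.01,
    n_connectors: int = 3,
    connector_part: int = 6,
    connector_p: float = 0.9,
    seed: int = 0,
) -> Network:
    """Dense blocks (weak cliques) plus bipartite connector modules,
    sparsely interconnected.

    Each block of ``block_size`` nodes is filled with internal links at
    density ``intra_p`` — dense but not complete, a weak clique whose
    edges are strong ties (their endpoints share most of the block).
    Each connector module is a near-complete bipartite graph between two
    parts of ``connector_part`` nodes (cross density ``connector_p``):
    the spoke model of a hub complex, in which a pair of same-part nodes
    shares all its neighbors yet those neighbors share nothing with
    either node — common links, not strong ties.  All remaining node
    pairs are linked independently with probability ``inter_p``.

    The two module types put the tie-strength machinery under real
    tension: same-part connector pairs have common-neighbor and
    resource-allocation scores rivalling true block pairs, but near-zero
    introduction weights.  At the frozen :data:`PLANTED_DEFAULTS` the
    census with auto-selected beta lands in the significant-PWCS regime.
    Set ``n_connectors=0`` for a pure union of dense blocks.
    """
    if block_size < 4:
        raise ValueError("block_size must be >= 4")
    if not 0.0 <= inter_p < intra_p <= 1.0:
        raise ValueError("need 0 <= inter_p < intra_p <= 1")
    rng = np.random.default_rng(seed)
    nodes: list[str] = []
    module_of: dict[str, tuple[str, int]] = {}
    edges: list[tuple[str, str]] = []
    for b in range(n_blocks):
        block = [f"b{b:02d}n{i:02d}" for i in range(block_size)]
        nodes += block
        for v in block:
            module_of[v] = ("block", b)
        for u, v in combinations(block, 2):
            if rng.random() < intra_p:
                edges.append((u, v))
    for c in range(n_connectors):
        left = [f"c{c:02d}L{i:02d}" for i in range(connector_part)]
        right = [f"c{c:02d}R{i:02d}" for i in range(connector_part)]
        nodes += left + right
        for v in left + right:
            module_of[v] = ("connector", c)
        for u in left:
            for v in right:
                if rng.random() < connector_p:
                    edges.append((u, v))
    for u, v in combinations(nodes, 2):
        if module_of[u] != module_of[v] and rng.random() < inter_p:
            edges.append((u, v))
    return Network(edges, nodes=nodes)


def non_pwcs_graph(
    m: int = 3, n_triangles: int = 10, n_bridges: int = 4, seed: int = 0
) -> Network:
    """An engineered fixture whose census lands in the non-PWCS regime.

    A complete tripartite graph K_{m,m,m} (every edge has exactly m
    common neighbors — strong ties — yet same-part leaf pairs never
    close) is combined with disjoint triangles (every edge has exactly 1
    common neighbor — common links — and every centered triple closes),
    plus a few random bridge edges so the mixed tie-pattern class is
    populated.  With beta between 1 and m-1 the census shows P3 > P1:
    closure is anti-associated with tie strength, the opposite of the
    PWCS phenomenon.
    """
    rng = np.random.default_rng(seed)
    edges: list[tuple[str, str]] = []
    parts = [[f"p{p}x{i:02d}" for i in range(m)] for p in range(3)]
    for a in range(3):
        for b in range(a + 1, 3):
            edges += [(u, v) for u in parts[a] for v in parts[b]]
    tri_nodes = []
    for t in range(n_triangles):
        tri = [f"t{t:02d}x{i}" for i in range(3)]
        tri_nodes += tri
        edges += [(tri[0], tri[1]), (tri[0], tri[2]), (tri[1], tri[2])]
    flat_parts = [v for part in parts for v in part]
    for _ in range(n_bridges):
        u = flat_parts[rng.integers(0, len(flat_parts))]
        v = tri_nodes[rng.integers(0, len(tri_nodes))]
        edges.append((u, v))
    return Network(edges)
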