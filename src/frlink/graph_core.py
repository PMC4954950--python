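"""Undirected simple-network container, edge-list I/O and topology summaries.

A :class:`Network` is a thin, validated wrapper around ``networkx.Graph``:
undirected, unweighted, no self-loops, no multi-edges, node identifiers
are opaque strings.  All higher-level modules (tie-strength census,
similarity indices, evaluation) operate on this container.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "TopologySummary",
    "read_edgelist",
    "write_edgelist",
    "common_neighbors",
    "summarize",
]


class EdgelistParseError(ValueError):
    """A malformed line was encountered while reading an edge list."""


class Network:
    """Undirected simple graph with opaque string node identifiers.

    Self-loops and duplicate edges are silently dropped at construction
    (each drop is logged at DEBUG level).  Isolated nodes are permitted:
    they arise naturally after train/test splitting.
    """

    __slots__ = ("_g",)

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
    ) -> None:
        g = nx.Graph()
        for u in nodes:
            g.add_node(str(u))
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                logger.debug("dropping self-loop at node %r", u)
                continue
            if g.has_edge(u, v):
                logger.debug("dropping duplicate edge (%r, %r)", u, v)
                continue
            g.add_edge(u, v)
        self._g = g

    # -- basic queries -------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Edge set with each edge in sorted-endpoint canonical order."""
        return {canonical_pair(u, v) for u, v in self._g.edges}

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_node(self, u: str) -> bool:
        return self._g.has_node(u)

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def neighbors(self, u: str) -> set[str]:
        """The neighbor set Gamma(u)."""
        self._require(u)
        return set(self._g[u])

    def degree(self, u: str) -> int:
        self._require(u)
        return self._g.degree[u]

    def __contains__(self, u: str) -> bool:
        return self._g.has_node(u)

    def __iter__(self) -> Iterator[str]:
        return iter(self._g.nodes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    def _require(self, u: str) -> None:
        if not self._g.has_node(u):
            raise KeyError(f"unknown node {u!r}")

    # -- conversion ----------------------------------------------------

    def to_networkx(self) -> nx.Graph:
        """A copy of the underlying ``networkx.Graph``."""
        return self._g.copy()

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        net = cls()
        for u in g.nodes:
            net._g.add_node(str(u))
        for u, v in g.edges:
            if u != v:
                net._g.add_edge(str(u), str(v))
        return net


def canonical_pair(u: str, v: str) -> tuple[str, str]:
    """Unordered node pair in canonical (sorted) order."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class TopologySummary:
    """Standard topology statistics of a network.

    ``clustering`` is the mean local clustering coefficient;
    ``transitivity`` (global triangle ratio) is reported alongside because
    summary tables in the link-prediction literature use either convention.
    ``heterogeneity`` is <k^2>/<k>^2, equal to 1 exactly for degree-regular
    graphs.
    """

    n_nodes: int
    n_edges: int
    mean_degree: float
    clustering: float
    transitivity: float
    assortativity: float
    heterogeneity: float


def read_edgelist(path: str | Path, delimiter: str | None = None) -> Network:
    """Read an undirected edge list from a text file.

    Each non-blank, non-comment line must carry at least two
    whitespace-separated (or ``delimiter``-separated) tokens; tokens past
    the second are ignored.  Lines starting with ``#`` and blank lines are
    skipped.  Node identifiers are preserved verbatim.  Self-loops and
    duplicate edges are dropped (logged).

    Raises
    ------
    EdgelistParseError
        If a line has fewer than two tokens (the message names the line).
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split(delimiter)
            if len(tokens) < 2:
                raise EdgelistParseError(
                    f"{path}:{lineno}: expected at least 2 tokens, got {len(tokens)}"
                )
            edges.append((tokens[0], tokens[1]))
    return Network(edges)


def write_edgelist(net: Network, path: str | Path, delimiter: str = "\t") -> None:
    """Write a network as a sorted text edge list (round-trip safe)."""
    path = Path(path)
    with path.open("w") as fh:
        for u, v in sorted(net.edges):
            fh.write(f"{u}{delimiter}{v}\n")


def common_neighbors(net: Network, u: str, v: str) -> set[str]:
    """Gamma(u) & Gamma(v).  Never contains u or v (no self-loops)."""
    if u == v:
        raise ValueError("common_neighbors requires two distinct nodes")
    return net.neighbors(u) & net.neighbors(v)


def summarize(net: Network) -> TopologySummary:
    """Compute the standard topology summary (N, M, <k>, C, r, H).

    Raises
    ------
    ValueError
        If the network has no edges (the statistics are undefined).
    """
    if net.n_edges == 0:
        raise ValueError("topology summary undefined for a network with no edges")
    g = net._g
    degrees = [d for _, d in g.degree()]
    mean_k = sum(degrees) / len(degrees)
    mean_k2 = sum(d * d for d in degrees) / len(degrees)
    try:
        with np.errstate(invalid="ignore"):
            r = nx.degree_assortativity_coefficient(g)
        if math.isnan(r):
            r = 0.0
    except (ValueError, ZeroDivisionError):
        # perfectly regular graphs have zero degree variance over edges
        r = 0.0
    return TopologySummary(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        mean_degree=mean_k,
        clustering=nx.average_clustering(g),
        transitivity=nx.transitivity(g),
        assortativity=float(r),
        heterogeneity=mean_k2 / mean_k**2,
    )
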