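"""Strong-tie labeling, triple census, PWCS regime and null models.

An edge (u, v) is a *strong-tie link* when its endpoints share strictly
more than ``beta`` common neighbors; otherwise it is a *common link*.
The census enumerates every centered triple (A; {B, C}) with A adjacent
to both leaves and asks, per tie pattern of the two center edges, how
often the leaf pair closes into a triangle:

    P1 = Pr(B ~ C | both center edges strong)
    P2 = Pr(B ~ C | exactly one center edge strong)
    P3 = Pr(B ~ C | neither center edge strong)

Networks where nodes attach preferentially to weak-clique structure
(PWCS) show P1 > P2 and P1 > P3; on degree-preserving null networks the
three probabilities flatten out (P1 ~ P2 ~ P3).
"""

from __future__ import annotations

import bisect
import logging
import random
import warnings
from dataclasses import dataclass, field

from frlink.graph_core import Network, canonical_pair, common_neighbors

logger = logging.getLogger(__name__)

__all__ = [
    "TieLabeling",
    "TripleCensus",
    "PwcsRegime",
    "UndefinedProbabilityError",
    "select_beta",
    "label_ties",
    "triple_census",
    "classify_regime",
    "null_model",
]

#: Configuration ids for connected three-node subgraphs, as a documented
#: convention: CS1..CS3 are open triples (center edges both-strong /
#: exactly-one-strong / both-common); CS4..CS7 are triangles with 3 / 1 /
#: 2 / 0 strong edges.  The convention is fixed by the closed-form
#: multiplicities: a CS4 triangle contributes 3 both-strong centered
#: triples and a CS6 triangle contributes exactly 1.
CONFIGURATION_IDS = ("CS1", "CS2", "CS3", "CS4", "CS5", "CS6", "CS7")


class UndefinedProbabilityError(ValueError):
    """A closure probability has an empty conditioning class."""


@dataclass(frozen=True)
class TieLabeling:
    """Per-edge strong/common labels under a common-neighbor threshold."""

    beta: int
    strong: frozenset[tuple[str, str]]  # canonical edge pairs

    def is_strong(self, u: str, v: str) -> bool:
        return canonical_pair(u, v) in self.strong

    @property
    def n_strong(self) -> int:
        return len(self.strong)


@dataclass(frozen=True)
class TripleCensus:
    """Counts of the seven triple configurations and closure probabilities.

    ``p1``/``p2``/``p3`` are ``None`` (undefined, never silently zero)
    when their conditioning class contains no centered triples.
    """

    beta: int
    counts: dict[str, int] = field(default_factory=dict)
    p1: float | None = None
    p2: float | None = None
    p3: float | None = None

    @property
    def probabilities(self) -> tuple[float | None, float | None, float | None]:
        return (self.p1, self.p2, self.p3)


@dataclass(frozen=True)
class PwcsRegime:
    """PWCS verdict: ``significant`` (P1 > P2 > P3), ``weak``
    (P1 > P3 >= P2), or ``non_pwcs`` (anything else)."""

    regime: str

    def __post_init__(self) -> None:
        if self.regime not in ("significant", "weak", "non_pwcs"):
            raise ValueError(f"unknown regime {self.regime!r}")


def _edge_cn_counts(net: Network) -> dict[tuple[str, str], int]:
    return {
        canonical_pair(u, v): len(common_neighbors(net, u, v))
        for u, v in net.edges
    }


def select_beta(net: Network) -> int:
    """Choose the threshold balancing strong-tie and common link counts.

    Scans beta over 0 .. max edge common-neighbor count and returns the
    value minimizing \\|#strong(beta) - #common(beta)\\|; ties break toward
    the smaller beta for determinism.
    """
    if net.n_edges == 0:
        raise ValueError("select_beta requires at least one edge")
    cn = sorted(_edge_cn_counts(net).values())
    m = len(cn)
    best_beta, best_gap = 0, m + 1
    for beta in range(max(cn) + 1):
        # strong edges: cn > beta (strict)
        n_common = bisect.bisect_right(cn, beta)
        gap = abs((m - n_common) - n_common)
        if gap < best_gap:
            best_beta, best_gap = beta, gap
    return best_beta


def label_ties(net: Network, beta: int) -> TieLabeling:
    """Label every edge strong (strictly more than ``beta`` common
    neighbors between its endpoints) or common."""
    if beta < 0:
        raise ValueError("beta must be a non-negative integer")
    strong = frozenset(
        e for e, c in _edge_cn_counts(net).items() if c > beta
    )
    return TieLabeling(beta=beta, strong=strong)


def triple_census(net: Network, labeling: TieLabeling) -> TripleCensus:
    """Enumerate centered triples and compute P1, P2, P3.

    A centered triple is (A; {B, C}) with A adjacent to both B and C and
    the leaf pair unordered.  Each triple is classed by how many of its
    two center edges are strong (2 / 1 / 0) and by whether the leaf edge
    (B, C) exists.  The configuration counts CS1..CS7 tally connected
    three-node subgraphs under the module-level convention; the closed-
    form multiplicities (a fully strong triangle holds 3 both-strong
    centered triples, a two-strong triangle holds 1) emerge from the
    enumeration rather than being applied by hand.
    """
    # centered-triple tallies: [n_strong_center_edges] -> [open, closed]
    tally = {2: [0, 0], 1: [0, 0], 0: [0, 0]}
    counts = dict.fromkeys(CONFIGURATION_IDS, 0)
    is_strong = labeling.is_strong

    for a in net:
        nbrs = sorted(net.neighbors(a))
        for i in range(len(nbrs)):
            b = nbrs[i]
            sb = is_strong(a, b)
            for j in range(i + 1, len(nbrs)):
                c = nbrs[j]
                n_str = sb + is_strong(a, c)
                closed = net.has_edge(b, c)
                tally[n_str][closed] += 1
                if not closed:
                    # open triple: this center is its unique center
                    counts[("CS3", "CS2", "CS1")[n_str]] += 1

    # triangles: count each once, classed by total strong edges
    seen: set[tuple[str, str, str]] = set()
    for u, v in net.edges:
        for w in common_neighbors(net, u, v):
            tri = tuple(sorted((u, v, w)))
            if tri in seen:
                continue
            seen.add(tri)
            s = (
                is_strong(tri[0], tri[1])
                + is_strong(tri[0], tri[2])
                + is_strong(tri[1], tri[2])
            )
            counts[{3: "CS4", 1: "CS5", 2: "CS6", 0: "CS7"}[s]] += 1

    ps: list[float | None] = []
    for n_str, name in ((2, "P1"), (1, "P2"), (0, "P3")):
        n_open, n_closed = tally[n_str]
        total = n_open + n_closed
        if total == 0:
            warnings.warn(
                f"{name} undefined: no centered triples with "
                f"{n_str} strong center edge(s) at beta={labeling.beta}",
                stacklevel=2,
            )
            ps.append(None)
        else:
            ps.append(n_closed / total)
    return TripleCensus(
        beta=labeling.beta, counts=counts, p1=ps[0], p2=ps[1], p3=ps[2]
    )


def classify_regime(census: TripleCensus) -> PwcsRegime:
    """Classify the PWCS regime from the census probabilities.

    Raises
    ------
    UndefinedProbabilityError
        If any of P1, P2, P3 is undefined; lower beta or reject the
        network in that case.
    """
    p1, p2, p3 = census.probabilities
    if p1 is None or p2 is None or p3 is None:
        raise UndefinedProbabilityError(
            "cannot classify regime with undefined closure probabilities; "
            "lower beta or reject the network"
        )
    if p1 > p2 > p3:
        return PwcsRegime("significant")
    if p1 > p3 >= p2:
        return PwcsRegime("weak")
    return PwcsRegime("non_pwcs")


def null_model(
    net: Network,
    n_swaps: int | None = None,
    seed: int = 0,
    max_tries_factor: int = 100,
) -> Network:
    """Degree-preserving randomization by double-edge swaps.

    Two edges (u, v), (x, y) with four distinct endpoints are replaced by
    (u, x), (v, y) when neither replacement already exists.  The default
    target is 10 successful swaps per edge.  If the attempt budget
    (``max_tries_factor * n_swaps`` proposals) runs out first, a warning
    reports the achieved swap count.
    """
    if net.n_edges < 2:
        raise ValueError("null_model requires at least 2 edges")
    if n_swaps is None:
        n_swaps = 10 * net.n_edges
    if n_swaps < 1:
        raise ValueError("n_swaps must be >= 1")

    rng = random.Random(seed)
    g = net.to_networkx()
    edges = list(g.edges)
    done = tries = 0
    budget = max_tries_factor * n_swaps
    while done < n_swaps and tries < budget:
        tries += 1
        i, j = rng.randrange(len(edges)), rng.randrange(len(edges))
        if i == j:
            continue
        u, v = edges[i]
        x, y = edges[j]
        if rng.random() < 0.5:
            x, y = y, x
        if len({u, v, x, y}) < 4:
            continue
        if g.has_edge(u, x) or g.has_edge(v, y):
            continue
        g.remove_edge(u, v)
        g.remove_edge(x, y)
        g.add_edge(u, x)
        g.add_edge(v, y)
        edges[i] = (u, x)
        edges[j] = (v, y)
        done += 1
    if done < n_swaps:
        warnings.warn(
            f"null_model achieved {done}/{n_swaps} swaps before the "
            f"attempt budget ran out",
            stacklevel=2,
        )
    return Network.from_networkx(g)
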