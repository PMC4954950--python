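"""Similarity indices for link prediction.

Baselines, for a non-adjacent pair (i, j) with common-neighbor set
``Gamma(i) & Gamma(j)`` and degrees k(l):

    CN_ij  = |Gamma(i) & Gamma(j)|
    AA_ij  = sum_l 1 / log k(l)
    RA_ij  = sum_l 1 / k(l)

The friend-recommendation (FR) family models link formation as a mutual
friend l *introducing* i to j.  The introducer never re-introduces j to
itself, nor any friend it already shares with j, so the introduction
probability is

    f_ilj = 1 / (k(l) - 1 - |Gamma(l) & Gamma(j)|)

and the directed weight f_ij sums f_ilj over the common neighbors of the
pair.  The symmetric index is S_FR = f_ij + f_ji.  GFR(alpha) scales the
shared-friend subtrahend with 0 <= alpha <= 1 (alpha=0 is rank-identical
to RA; alpha=1 is FR without the -1), SFR amplifies strong-tie
contributions further, and MFR dispatches between SFR / FR / RA by the
network's PWCS regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from frlink.graph_core import Network, canonical_pair, common_neighbors
from frlink.tie_strength import TripleCensus, classify_regime

__all__ = [
    "ScoreTable",
    "score_cn",
    "score_aa",
    "score_ra",
    "intro_probability",
    "intro_weight",
    "score_fr",
    "score_gfr",
    "score_sfr",
    "score_mfr",
]

Pair = tuple[str, str]


@dataclass(frozen=True)
class ScoreTable:
    """Similarity scores for a set of candidate node pairs.

    ``scores`` maps canonical (sorted) node pairs to non-negative reals;
    pairs without common neighbors score exactly 0 under every index in
    this family.  ``params`` records index parameters (alpha, beta, the
    resolved MFR branch, ...).
    """

    index_name: str
    scores: dict[Pair, float]
    params: dict = field(default_factory=dict)

    def score(self, u: str, v: str) -> float:
        return self.scores.get(canonical_pair(u, v), 0.0)

    def __len__(self) -> int:
        return len(self.scores)


def _check_pair(net: Network, u: str, v: str, require_nonadjacent: bool) -> None:
    for x in (u, v):
        if x not in net:
            raise KeyError(f"unknown node {x!r}")
    if u == v:
        raise ValueError(f"pair ({u!r}, {u!r}) is not a valid node pair")
    if require_nonadjacent and net.has_edge(u, v):
        raise ValueError(
            f"pair ({u!r}, {v!r}) is adjacent in the scoring graph; "
            "only nonexistent links are scored"
        )


def _table(
    net: Network,
    pairs: Iterable[Pair],
    name: str,
    term,
    params: dict | None = None,
    require_nonadjacent: bool = False,
) -> ScoreTable:
    scores: dict[Pair, float] = {}
    for u, v in pairs:
        _check_pair(net, u, v, require_nonadjacent)
        scores[canonical_pair(u, v)] = term(u, v)
    return ScoreTable(index_name=name, scores=scores, params=params or {})


def score_cn(net: Network, pairs: Iterable[Pair]) -> ScoreTable:
    """Common-neighbor count."""
    return _table(
        net, pairs, "CN", lambda u, v: float(len(common_neighbors(net, u, v)))
    )


def score_aa(net: Network, pairs: Iterable[Pair]) -> ScoreTable:
    """Adamic-Adar: common neighbors weighted by 1/log degree."""
    return _table(
        net,
        pairs,
        "AA",
        lambda u, v: sum(
            1.0 / math.log(net.degree(l)) for l in common_neighbors(net, u, v)
        ),
    )


def score_ra(net: Network, pairs: Iterable[Pair]) -> ScoreTable:
    """Resource allocation: common neighbors weighted by 1/degree."""
    return _table(
        net,
        pairs,
        "RA",
        lambda u, v: sum(
            1.0 / net.degree(l) for l in common_neighbors(net, u, v)
        ),
    )


def intro_probability(net: Network, i: str, l: str, j: str) -> float:
    """Probability f_ilj of l introducing i to j.

    l picks uniformly among its neighbors other than j itself and the
    friends it already shares with j::

        f_ilj = 1 / (k(l) - 1 - |Gamma(l) & Gamma(j)|)

    Requires l to be a common neighbor of i and j, with (i, j)
    non-adjacent; then i itself is a neighbor of l counted by neither
    subtrahend, so the denominator is at least 1.
    """
    nbrs_l = net.neighbors(l)
    if i not in nbrs_l or j not in nbrs_l:
        raise ValueError(
            f"node {l!r} is not a common neighbor of {i!r} and {j!r}"
        )
    if net.has_edge(i, j):
        raise ValueError(
            f"pair ({i!r}, {j!r}) is adjacent; introduction is defined for "
            "nonexistent links only"
        )
    return 1.0 / (net.degree(l) - 1 - len(nbrs_l & net.neighbors(j)))


def intro_weight(net: Network, i: str, j: str) -> float:
    """Directed weight f_ij: sum of f_ilj over common neighbors of (i, j).

    Grows with the number of common neighbors and may exceed 1 (hence a
    weight, not a probability).  Empty sum (no common neighbors) is 0.
    """
    _check_pair(net, i, j, require_nonadjacent=True)
    return sum(
        intro_probability(net, i, l, j) for l in common_neighbors(net, i, j)
    )


def score_fr(net: Network, pairs: Iterable[Pair]) -> ScoreTable:
    """Friend-recommendation index S_FR = f_ij + f_ji (symmetric)."""
    return _table(
        net,
        pairs,
        "FR",
        lambda u, v: intro_weight(net, u, v) + intro_weight(net, v, u),
        require_nonadjacent=True,
    )


def score_gfr(net: Network, pairs: Iterable[Pair], alpha: float) -> ScoreTable:
    """Generalized FR interpolating between RA-like and FR-like scoring.

        S_GFR_ij = sum_l [ 1/(k(l) - alpha*|Gamma(l) & Gamma(j)|)
                         + 1/(k(l) - alpha*|Gamma(l) & Gamma(i)|) ]

    At alpha=0 every score equals exactly 2*RA (rank-identical to RA; the
    symmetric two-term form keeps the alpha=1 limit structurally aligned
    with FR's two directed weights).  Denominators stay >= 1 for
    alpha <= 1 because a common neighbor l of a non-adjacent pair shares
    at most k(l) - 1 neighbors with either endpoint.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")

    def term(u: str, v: str) -> float:
        total = 0.0
        nbrs_u, nbrs_v = net.neighbors(u), net.neighbors(v)
        for l in nbrs_u & nbrs_v:
            k = net.degree(l)
            nbrs_l = net.neighbors(l)
            total += 1.0 / (k - alpha * len(nbrs_l & nbrs_v))
            total += 1.0 / (k - alpha * len(nbrs_l & nbrs_u))
        return total

    return _table(
        net, pairs, "GFR", term, {"alpha": alpha}, require_nonadjacent=True
    )


def score_sfr(net: Network, pairs: Iterable[Pair]) -> ScoreTable:
    """Strong friend recommendation.

    The GFR(alpha=1) per-neighbor term written over the common
    denominator is (2 k(l) - c_i - c_j) / ((k(l) - c_j)(k(l) - c_i)) with
    c_x = |Gamma(l) & Gamma(x)|; SFR drops the two subtrahends from that
    numerator so strong-tie introducers count fully::

        S_SFR_ij = sum_l 2 k(l) / ((k(l) - c_j) (k(l) - c_i))

    Consequently S_SFR >= S_GFR(alpha=1) pairwise.
    """

    def term(u: str, v: str) -> float:
        total = 0.0
        nbrs_u, nbrs_v = net.neighbors(u), net.neighbors(v)
        for l in nbrs_u & nbrs_v:
            k = net.degree(l)
            nbrs_l = net.neighbors(l)
            cu = len(nbrs_l & nbrs_u)
            cv = len(nbrs_l & nbrs_v)
            total += 2.0 * k / ((k - cv) * (k - cu))
        return total

    return _table(net, pairs, "SFR", term, require_nonadjacent=True)


_MFR_BRANCHES = {"significant": score_sfr, "weak": score_fr, "non_pwcs": score_ra}


def score_mfr(
    net: Network, pairs: Iterable[Pair], census: TripleCensus
) -> ScoreTable:
    """Mixed FR index: dispatch on the PWCS regime of the scoring graph.

    significant (P1 > P2 > P3) -> SFR; weak (P1 > P3 >= P2) -> FR;
    non-PWCS -> RA.  The census must come from the same (training)
    network the pairs are scored on.  The resolved branch and regime are
    recorded in ``params``.
    """
    regime = classify_regime(census).regime
    delegate = _MFR_BRANCHES[regime]
    table = delegate(net, list(pairs))
    return ScoreTable(
        index_name="MFR",
        scores=table.scores,
        params={
            "regime": regime,
            "branch": table.index_name,
            "beta": census.beta,
        },
    )
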