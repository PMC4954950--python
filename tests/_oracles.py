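"""Independent brute-force reference implementations for cross-checking.

Everything here works directly on an adjacency dict built from an edge
set, deliberately avoiding the package's Network/ScoreTable machinery so
the two code paths share nothing but the input graph.
"""

from __future__ import annotations

import math
from itertools import combinations


def adjacency(edges) -> dict:
    adj: dict[str, set[str]] = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    return adj


def brute_census(nodes, edges, beta):
    """Closure probabilities by scanning every 3-subset of nodes."""
    adj = adjacency(edges)
    for n in nodes:
        adj.setdefault(n, set())

    def strong(u, v):
        return len(adj[u] & adj[v]) > beta

    tallies = {2: [0, 0], 1: [0, 0], 0: [0, 0]}  # n_strong -> [open, closed]
    for a, b, c in combinations(sorted(nodes), 3):
        for center, x, y in ((a, b, c), (b, a, c), (c, a, b)):
            if x in adj[center] and y in adj[center]:
                n_str = strong(center, x) + strong(center, y)
                tallies[n_str][y in adj[x]] += 1
    out = []
    for k in (2, 1, 0):
        n_open, n_closed = tallies[k]
        out.append(None if n_open + n_closed == 0 else n_closed / (n_open + n_closed))
    return tuple(out)


def brute_scores(nodes, edges, index, alpha=None):
    """Score every non-adjacent pair under one index, by direct formula."""
    adj = adjacency(edges)
    for n in nodes:
        adj.setdefault(n, set())

    def k(x):
        return len(adj[x])

    def one(i, j):
        cns = adj[i] & adj[j]
        if index == "cn":
            return float(len(cns))
        if index == "aa":
            return sum(1 / math.log(k(l)) for l in cns)
        if index == "ra":
            return sum(1 / k(l) for l in cns)
        if index == "fr":
            return sum(
                1 / (k(l) - 1 - len(adj[l] & adj[j]))
                + 1 / (k(l) - 1 - len(adj[l] & adj[i]))
                for l in cns
            )
        if index == "gfr":
            return sum(
                1 / (k(l) - alpha * len(adj[l] & adj[j]))
                + 1 / (k(l) - alpha * len(adj[l] & adj[i]))
                for l in cns
            )
        if index == "sfr":
            return sum(
                2 * k(l)
                / ((k(l) - len(adj[l] & adj[j])) * (k(l) - len(adj[l] & adj[i])))
                for l in cns
            )
        raise ValueError(index)

    return {
        (u, v): one(u, v)
        for u, v in combinations(sorted(nodes), 2)
        if v not in adj[u]
    }


def brute_auc(score_of, test, universe):
    """All-pairs AUC with half credit for ties."""
    missing = [p for p in universe if p in test]
    nonexist = [p for p in universe if p not in test]
    wins = 0.0
    for a in missing:
        for b in nonexist:
            if score_of(a) > score_of(b):
                wins += 1
            elif score_of(a) == score_of(b):
                wins += 0.5
    return wins / (len(missing) * len(nonexist))
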