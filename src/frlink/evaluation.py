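"""Train/test splitting, AUC and Precision@L, alpha sweeps, rank comparison.

The protocol: hide a random 10% of links (the probe set E_P), score every
candidate pair — all node pairs not linked in the training graph — and
ask how well the index ranks the hidden links above the truly nonexistent
ones.  AUC is the probability that a random missing link outscores a
random nonexistent link (half credit for ties); Precision@L is the
fraction of true missing links among the L top-ranked candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from frlink.graph_core import Network, canonical_pair
from frlink.similarity import Pair, ScoreTable, score_gfr, score_ra
from frlink import similarity as _sim
from frlink.tie_strength import label_ties, select_beta, triple_census

__all__ = [
    "SplitSpec",
    "EvalResult",
    "split_edges",
    "candidate_pairs",
    "auc",
    "precision_at",
    "evaluate_index",
    "alpha_sweep",
    "rank_percentiles",
]


@dataclass(frozen=True)
class SplitSpec:
    """Random edge split: ``train_fraction`` of links kept for training."""

    train_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class EvalResult:
    """Metrics and provenance for one prediction run."""

    index_name: str
    auc: float
    precision: float
    L: int
    n_comparisons: int
    seed: int
    params: dict = field(default_factory=dict)


def split_edges(
    net: Network, spec: SplitSpec
) -> tuple[Network, set[Pair]]:
    """Randomly partition E into a training network and a probe edge set.

    |E_T| = round(train_fraction * M); the training network retains every
    node of the original (isolated nodes are legal).  Deterministic per
    seed.
    """
    if net.n_edges < 10:
        raise ValueError("split_edges requires at least 10 edges")
    edges = sorted(net.edges)
    n_train = round(spec.train_fraction * len(edges))
    if n_train == len(edges):
        raise ValueError("split leaves an empty test set; lower train_fraction")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(edges))
    train_edges = [edges[i] for i in perm[:n_train]]
    test_edges = {edges[i] for i in perm[n_train:]}
    train = Network(train_edges, nodes=net.nodes)
    return train, test_edges


def candidate_pairs(train: Network) -> list[Pair]:
    """All node pairs absent from the training network (U - E_T)."""
    return [
        canonical_pair(u, v)
        for u, v in combinations(sorted(train.nodes), 2)
        if not train.has_edge(u, v)
    ]


def auc(
    scores: ScoreTable,
    test: set[Pair],
    universe: Sequence[Pair],
    n: int = 100_000,
    seed: int = 0,
    exact: bool = True,
) -> float:
    """AUC of a score table over a candidate universe.

    Exact mode computes the full expectation over all
    (missing, nonexistent) pairs via midranks (ties earn half credit).
    Sampled mode draws ``n`` independent comparisons with a seeded RNG
    and reports (n' + 0.5 n'') / n; it converges to the exact value as n
    grows.  Pairs absent from the score table score 0.
    """
    test = {canonical_pair(*p) for p in test}
    missing = [p for p in universe if p in test]
    nonexist = [p for p in universe if p not in test]
    if not missing or not nonexist:
        raise ValueError("AUC requires non-empty missing and nonexistent sets")
    s_miss = np.array([scores.score(*p) for p in missing])
    s_non = np.array([scores.score(*p) for p in nonexist])
    if exact:
        ranks = rankdata(np.concatenate([s_miss, s_non]))
        u_stat = ranks[: len(s_miss)].sum() - len(s_miss) * (len(s_miss) + 1) / 2
        return float(u_stat / (len(s_miss) * len(s_non)))
    rng = np.random.default_rng(seed)
    a = s_miss[rng.integers(0, len(s_miss), size=n)]
    b = s_non[rng.integers(0, len(s_non), size=n)]
    return float(((a > b).sum() + 0.5 * (a == b).sum()) / n)


def precision_at(
    scores: ScoreTable,
    test: set[Pair],
    universe: Sequence[Pair],
    L: int = 100,
    seed: int = 0,
) -> float:
    """Precision@L: fraction of probe links among the top-L candidates.

    Candidates are sorted by descending score; ties (including the mass
    of zero-scoring pairs at the boundary) are broken by a seeded random
    permutation, making the result an unbiased draw from the tie
    expectation yet reproducible per seed.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if len(universe) < L:
        warnings.warn(
            f"only {len(universe)} candidates available for top-{L}; using all",
            stacklevel=2,
        )
        L = len(universe)
    test = {canonical_pair(*p) for p in test}
    rng = np.random.default_rng(seed)
    s = np.array([scores.score(*p) for p in universe])
    tiebreak = rng.permutation(len(universe))
    order = np.lexsort((tiebreak, -s))
    hits = sum(1 for idx in order[:L] if universe[idx] in test)
    return hits / L


_INDEX_DISPATCH: dict[str, Callable] = {
    "cn": _sim.score_cn,
    "aa": _sim.score_aa,
    "ra": _sim.score_ra,
    "fr": _sim.score_fr,
    "sfr": _sim.score_sfr,
}


def _score_training_graph(
    train: Network,
    index: str,
    alpha: float | None = None,
    beta: int | None = None,
) -> ScoreTable:
    """Score all distance-2 candidate pairs of the training graph.

    Pairs at distance > 2 score 0 under every index in this family and
    are omitted from the sparse table (``ScoreTable.score`` returns 0
    for them).
    """
    index = index.lower()
    pairs = sorted(
        {
            canonical_pair(u, w)
            for v in train
            for u in train.neighbors(v)
            for w in train.neighbors(v)
            if u < w and not train.has_edge(u, w)
        }
    )
    if index == "gfr":
        if alpha is None:
            raise ValueError("GFR requires alpha")
        return score_gfr(train, pairs, alpha=alpha)
    if index == "mfr":
        b = select_beta(train) if beta is None else beta
        census = triple_census(train, label_ties(train, b))
        return _sim.score_mfr(train, pairs, census)
    if index not in _INDEX_DISPATCH:
        raise ValueError(f"unknown index {index!r}")
    return _INDEX_DISPATCH[index](train, pairs)


def evaluate_index(
    net: Network,
    index: str,
    spec: SplitSpec,
    L: int = 100,
    alpha: float | None = None,
    beta: int | None = None,
    exact_auc: bool | None = None,
    n_auc: int = 100_000,
) -> EvalResult:
    """One full prediction run: split, score, AUC + Precision@L.

    For MFR the tie-strength census (beta selection and regime) is
    computed on the training graph only — never the full network — so no
    probe information leaks into the dispatch decision.  AUC defaults to
    exact mode unless the candidate universe exceeds 5e6 pairs.
    """
    train, test = split_edges(net, spec)
    universe = candidate_pairs(train)
    if exact_auc is None:
        exact_auc = len(universe) < 5_000_000
    table = _score_training_graph(train, index, alpha=alpha, beta=beta)
    a = auc(table, test, universe, n=n_auc, seed=spec.seed, exact=exact_auc)
    p = precision_at(table, test, universe, L=L, seed=spec.seed)
    return EvalResult(
        index_name=table.index_name,
        auc=a,
        precision=p,
        L=min(L, len(universe)),
        n_comparisons=(len(test) * (len(universe) - len(test))) if exact_auc else n_auc,
        seed=spec.seed,
        params=dict(table.params),
    )


def alpha_sweep(
    net: Network,
    alphas: Sequence[float],
    spec: SplitSpec,
    replicates: int = 1,
    L: int = 100,
) -> pd.DataFrame:
    """Mean Precision@L of GFR(alpha) over seeded split replicates.

    Returns a tidy frame (alpha, mean_precision, sd_precision, regime)
    where ``regime`` is the PWCS regime of the full network, enabling
    regime/shape comparison of the sweep curves.
    """
    from frlink.tie_strength import classify_regime

    beta = select_beta(net)
    census = triple_census(net, label_ties(net, beta))
    try:
        regime = classify_regime(census).regime
    except Exception:
        regime = "undefined"
    rows = []
    for alpha in alphas:
        precs = []
        for r in range(replicates):
            run_spec = SplitSpec(spec.train_fraction, seed=spec.seed + r)
            train, test = split_edges(net, run_spec)
            universe = candidate_pairs(train)
            table = _score_training_graph(train, "gfr", alpha=alpha)
            precs.append(
                precision_at(table, test, universe, L=L, seed=run_spec.seed)
            )
        rows.append(
            {
                "alpha": alpha,
                "mean_precision": float(np.mean(precs)),
                "sd_precision": float(np.std(precs, ddof=1)) if len(precs) > 1 else 0.0,
                "regime": regime,
            }
        )
    return pd.DataFrame(rows)


def rank_percentiles(
    scores_a: ScoreTable,
    scores_b: ScoreTable,
    test: set[Pair],
    universe: Sequence[Pair],
) -> pd.DataFrame:
    """Per-pair top-percentage ranks under two indices.

    For each candidate pair, the percentile is its descending-score
    midrank divided by the universe size, times 100 — small values mean
    top-ranked.  Enables scatter export comparing how two indices rank
    the same candidates (probe links flagged by ``is_test``).
    """
    test = {canonical_pair(*p) for p in test}
    s_a = np.array([scores_a.score(*p) for p in universe])
    s_b = np.array([scores_b.score(*p) for p in universe])
    n = len(universe)
    pct_a = rankdata(-s_a) / n * 100.0
    pct_b = rankdata(-s_b) / n * 100.0
    return pd.DataFrame(
        {
            "node_i": [p[0] for p in universe],
            "node_j": [p[1] for p in universe],
            "pct_a": pct_a,
            "pct_b": pct_b,
            "is_test": [p in test for p in universe],
        }
    )
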