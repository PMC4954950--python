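# Methods

`frlink` implements link prediction for undirected, unweighted simple
networks built around a single structural observation: in many real
networks — protein interaction maps, neural wiring, food webs, social
graphs — nodes attach preferentially to *weak cliques*, dense but not
necessarily complete node subsets. We call this PWCS (preferential
attachment to weak-clique structure). This note records the model, the
estimators, the numerical conventions, and the places where the design
was genuinely open.

## Tie strength and the triple census

Fix a threshold β ≥ 0. An edge (u, v) is a **strong-tie link** when its
endpoints share strictly more than β common neighbors,
|Γ(u) ∩ Γ(v)| > β, and a **common link** otherwise. β is selected per
network so that the two classes are as close to balanced as possible;
ties between equally balanced thresholds break toward the smaller β, for
determinism. The balanced choice makes tie labels comparable across
networks of very different density.

A **centered triple** is (A; {B, C}) with A adjacent to both leaves and
the leaf pair unordered. Classing each triple by how many of its two
center edges are strong and by whether the leaf edge exists gives the
three closure probabilities

- P1 = Pr(B ~ C | both center edges strong),
- P2 = Pr(B ~ C | exactly one strong),
- P3 = Pr(B ~ C | neither strong).

The regime is **significant** when P1 > P2 > P3 (strict), **weak** when
P1 > P3 ≥ P2, and **non-PWCS** otherwise. A conditioning class with no
triples yields an *undefined* probability (surfaced as `None` plus a
warning, never silently zeroed): Table-style outputs must be able to
distinguish "0 closed among many" from "no triples at all".

The seven connected three-node configurations are tallied alongside
(CS1–CS3 open triples with 2/1/0 strong center edges; CS4–CS7 triangles
with 3/1/2/0 strong edges). The census enumerates centered triples
directly, so the closed-form multipliers — a fully strong triangle holds
three both-strong centered triples, a two-strong triangle exactly one —
emerge from the enumeration instead of being applied by hand; a unit
test pins the equivalence P1 = (3·N_CS4 + N_CS6)/(3·N_CS4 + N_CS6 + N_CS1).

**A degeneracy worth knowing.** If β = 0 then P2 = P3 = 0 *identically*
in every network: a closed triple's leaf is a common neighbor of both
center edges, so both are strong by definition. Any quantitative reading
of "the census flattens on randomized networks" must therefore be made
at β ≥ 1, which desk-scale sparse graphs (where the balanced β is 0)
cannot deliver. This is why the null-model checks below compare
*spreads* rather than asserting three-way equality.

## Null model

The reference distribution for the census is a degree-preserving
randomization: repeated double-edge swaps (u,v),(x,y) → (u,x),(v,y),
rejected when they would create a self-loop or multi-edge. Default: 10
successful swaps per edge, seeded, with a bounded proposal budget (100
proposals per requested swap) that warns rather than raises when
exhausted. β is re-selected on the rewired network, treating the null as
a network in its own right; holding the original β would empty the
strong class entirely on small sparse graphs. On the planted benchmark
the original census spread P1 − P3 ≈ 0.85 collapses to ≈ 0.4–0.55 on
every replicate — the residual spread is the β = 0 degeneracy plus the
finite-size coupling between closure and the common-neighbor count (a
closing leaf adds one common neighbor to each center edge, a
non-negligible shift when typical counts are O(1)).

## Similarity indices

For a non-adjacent pair (i, j) with common neighbors l ∈ Γ(i) ∩ Γ(j),
degrees k(l):

- CN = |Γ(i) ∩ Γ(j)|; AA = Σ 1/log k(l); RA = Σ 1/k(l).
- **FR** (friend recommendation): the introducer l presents i to j
  choosing uniformly among its neighbors *excluding j itself and the
  friends it already shares with j*, so
  f_ilj = 1/(k(l) − 1 − |Γ(l) ∩ Γ(j)|); the directed weight
  f_ij = Σ_l f_ilj (a weight, not a probability — it grows with the
  number of common neighbors and may exceed 1); the index is the
  symmetric sum S^FR = f_ij + f_ji. The denominator is always ≥ 1
  because i is a neighbor of l counted by neither subtrahend. We use the
  sum rather than the mean of the two directed weights; symmetry is the
  only constraint and constant factors never change a ranking.
- **GFR(α)**, 0 ≤ α ≤ 1, scales the shared-friend subtrahend:
  S^GFR = Σ_l [1/(k(l) − α|Γ(l) ∩ Γ(j)|) + 1/(k(l) − α|Γ(l) ∩ Γ(i)|)].
  At α = 0 every score is exactly 2·RA — the doubled, two-term form is
  deliberate so that α = 1 keeps FR's two-directional structure; the
  factor 2 is rank-irrelevant. GFR is continuous and non-decreasing in α
  pair by pair (each denominator is non-increasing in α), and its
  denominators stay ≥ 1 for α ≤ 1.
- **SFR** rewrites the GFR(1) per-neighbor term over a common
  denominator and drops the two subtracted common-neighbor counts from
  the numerator: Σ_l 2k(l) / [(k(l) − |Γ(l)∩Γ(j)|)(k(l) − |Γ(l)∩Γ(i)|)].
  Dropping positive subtrahends can only raise the term, so
  SFR ≥ GFR(1) ≥ GFR(0) pairwise.
- **MFR** dispatches on the regime measured on the *scoring* graph:
  significant → SFR, weak → FR, non-PWCS → RA. In evaluation the census
  (β selection included) is computed on the training graph only — the
  probe set must not leak into the dispatch decision.

Only pairs non-adjacent in the scoring graph may be scored by the FR
family (requesting an adjacent pair is a contract error, not a silent
zero); every index in the family is supported on common neighbors, so
pairs at distance > 2 score 0 and are omitted from the sparse tables.

## Evaluation protocol

A split hides a uniformly random 10% of edges (training fraction 0.9 by
default, |E^T| = round(0.9·M), all nodes retained, deterministic per
seed; no connectivity repair). Candidates are all pairs absent from the
training graph. **AUC** is the probability that a random hidden link
outscores a random nonexistent link, half credit for ties; the default
is the exact expectation via midranks (Mann–Whitney), with seeded
sampling (n′ + 0.5n″)/n available and used automatically above 5·10⁶
candidate pairs. **Precision@L** (L = 100 default) counts hidden links
among the top-L candidates; score ties at the boundary — including the
mass of zero scores — are broken by a seeded random permutation, an
unbiased draw from the tie expectation that keeps runs bitwise
reproducible. Both metrics are invariant under strictly monotone score
transforms. The α-sweep reports mean Precision of GFR(α) over seeded
split replicates next to the full network's regime.

## Synthetic benchmarks

`fig3_graphs()` and `fig4_graph()` are minimal 5- and 7-node
introduction scenarios on which every f-value is hand-checkable (and
pinned in tests to 1e-12).

`gen_erdos_renyi` is the no-structure control. At the sparse test
setting (n = 200, p = 0.05) its balanced β is 0, so by the degeneracy
above its census is never significant (20/20 seeds observed
non-significant); it is *not* three-way flat at this scale.

`gen_planted_weak_clique` is the frozen benchmark and emulates the two
module archetypes seen in protein-complex maps: (a) dense blocks —
weak cliques, 12 blocks of 8 nodes at intra-density 0.9, whose edges are
strong ties; and (b) bipartite connector modules — the spoke model of a
hub complex, 3 modules with 6+6 parts at cross-density 0.9. A same-part
connector pair shares essentially all of its neighbors (high CN/RA
score) while those shared neighbors share nothing with either endpoint
(near-zero introduction weight): exactly the candidate class on which a
pure degree penalty misranks and tie-strength awareness does not.
Remaining pairs are noise at probability 0.01. Parameters were chosen
once by running the census and the evaluation at a handful of settings
and then frozen: the regime is significant-PWCS in 20/20 generator
seeds, and the benchmark expresses a stable FR-over-RA precision margin.

A finding that shaped this design: in a *homogeneous* planted-block
model (blocks of one size and density plus noise), removed test links
and never-links inside a block are statistically exchangeable, so every
common-neighbor index earns the same Precision up to noise — RA and FR
order candidate blocks identically (RA's intra score ≈ intra density p,
FR's ≈ 2p/(1−p), both monotone in p). Pure-block benchmarks therefore
cannot separate the indices, whatever their parameters; separation
requires a candidate class where coarse co-neighborhood and tie
strength disagree, which the connector modules supply.

`non_pwcs_graph()` engineers the opposite regime (closure
anti-associated with tie strength): complete tripartite K_{3,3,3} edges
are strong yet same-part leaves never close, disjoint triangles are
common links that always close, and a few bridges populate the mixed
class; census at auto-β ≈ (0.60, 0.00, 0.79).

What these generators do *not* emulate: heavy-tailed degree sequences,
degree–degree correlations, overlapping modules, and the scale of real
interactomes. Passing tests on them demonstrates the mechanisms —
identities, dispatch, direction of effect — not the magnitude of any
real-network accuracy number.

## Numerical conventions and edge cases

- Node identifiers are opaque strings, preserved verbatim from edge
  lists; "#" comments and blank lines skipped; self-loops and duplicate
  lines dropped with a log record.
- Clustering in the topology summary is the mean local coefficient;
  global transitivity is reported alongside since summary tables in the
  benchmark literature use either convention.
- Exact float equality is never asserted across different summation
  orders; worked-example values are pinned at 1e-12.
- Degenerate inputs: edgeless graphs are rejected by the summary and by
  β selection; splits require ≥ 10 edges and a non-empty probe set;
  AUC requires non-empty probe and nonexistent sets; undefined census
  probabilities poison regime classification loudly.
- All randomness (splits, tie-breaks, null swaps, generators, sampled
  AUC) flows through explicit integer seeds; identical seeds give
  bitwise-identical outputs.

## Problem sizes

The test suite and the reproduction script run on graphs of 5–200 nodes
(the frozen benchmark has 132 nodes, ≈ 490 edges), 20 split replicates,
20 null replicates, and 10⁵ sampled AUC comparisons — sizes at which the
exact-mode metrics are affordable and every oracle cross-check can run
exhaustively.

## Known limitations

- The FR family is undefined-by-design for adjacent pairs and blind to
  pairs beyond distance 2; it cannot rank candidates in locally
  tree-like regions (all scores 0 there, ties broken at random).
- f_ilj is extremely sensitive when k(l) − 1 − |Γ(l)∩Γ(j)| is small; in
  near-clique neighborhoods a single edge can change a score severalfold.
- β selection balances *counts*, not any statistical criterion; on
  graphs where most edges share no neighbors the balanced β is 0 and the
  census degenerates as described.
- Weighted, directed, bipartite and multigraph inputs are out of scope.
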