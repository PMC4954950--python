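import math
import random
import warnings

import pytest

from frlink.graph_core import Network
from frlink.similarity import (
    intro_probability,
    intro_weight,
    score_aa,
    score_cn,
    score_fr,
    score_gfr,
    score_mfr,
    score_ra,
    score_sfr,
)
from frlink.tie_strength import TripleCensus, label_ties, select_beta, triple_census
from frlink.synthetic import gen_erdos_renyi, non_pwcs_graph

from _oracles import brute_scores
from conftest import random_graph


def nonadjacent_pairs(net):
    nodes = sorted(net.nodes)
    return [
        (u, v)
        for i, u in enumerate(nodes)
        for v in nodes[i + 1:]
        if not net.has_edge(u, v)
    ]


class TestBaselines:
    def test_cn_on_fig4(self, fig4):
        assert score_cn(fig4, [("1", "2")]).score("1", "2") == 2

    def test_aa_single_common_neighbor(self):
        net = Network([("a", "l"), ("b", "l")])
        assert score_aa(net, [("a", "b")]).score("a", "b") == pytest.approx(
            1 / math.log(2)
        )

    def test_ra_on_fig4(self, fig4):
        # common neighbors 3 (degree 5) and 4 (degree 4): 1/5 + 1/4
        assert score_ra(fig4, [("1", "2")]).score("1", "2") == pytest.approx(0.45)

    def test_no_common_neighbors_scores_zero(self):
        net = Network([("a", "b"), ("c", "d")])
        for scorer in (score_cn, score_aa, score_ra, score_fr, score_sfr):
            assert scorer(net, [("a", "c")]).score("a", "c") == 0.0


class TestIntroduction:
    def test_fig3_probabilities(self, fig3):
        a, b, c = fig3
        assert intro_probability(a, "1", "2", "3") == pytest.approx(1 / 3)
        assert intro_probability(b, "1", "2", "3") == pytest.approx(1 / 2)
        assert intro_probability(c, "1", "2", "3") == pytest.approx(1.0)

    def test_fig4_probabilities(self, fig4):
        assert intro_probability(fig4, "2", "3", "1") == pytest.approx(1 / 3)
        assert intro_probability(fig4, "2", "4", "1") == pytest.approx(1 / 2)
        assert intro_probability(fig4, "1", "3", "2") == pytest.approx(1 / 2)
        assert intro_probability(fig4, "1", "4", "2") == pytest.approx(1 / 2)

    def test_fig4_weights(self, fig4):
        assert intro_weight(fig4, "2", "1") == pytest.approx(5 / 6)
        assert intro_weight(fig4, "1", "2") == pytest.approx(1.0)

    def test_not_a_common_neighbor_rejected(self, fig4):
        with pytest.raises(ValueError):
            intro_probability(fig4, "1", "6", "2")

    def test_adjacent_pair_rejected(self, fig4):
        with pytest.raises(ValueError):
            intro_weight(fig4, "3", "4")

    def test_empty_sum_is_zero(self):
        net = Network([("a", "b"), ("c", "d")])
        assert intro_weight(net, "a", "c") == 0.0


class TestFr:
    def test_fig4_value(self, fig4):
        assert score_fr(fig4, [("1", "2")]).score("1", "2") == pytest.approx(11 / 6)

    def test_resolution_over_fig3_variants(self, fig3):
        # CN/AA/RA cannot distinguish the three introduction scenarios for
        # the focal pair, FR strictly orders them by tie strength
        focal = [("1", "3")]
        for scorer in (score_cn, score_aa, score_ra):
            vals = [scorer(g, focal).score("1", "3") for g in fig3]
            assert vals[0] == vals[1] == vals[2]
        fr = [score_fr(g, focal).score("1", "3") for g in fig3]
        assert fr[0] < fr[1] < fr[2]

    def test_symmetric_on_random_pairs(self):
        rng = random.Random(17)
        net = random_graph(rng)
        for u, v in nonadjacent_pairs(net):
            t = score_fr(net, [(u, v)])
            assert t.score(u, v) == t.score(v, u)


class TestGfr:
    def test_alpha_zero_is_twice_ra(self):
        rng = random.Random(2)
        for _ in range(10):
            net = random_graph(rng)
            pairs = nonadjacent_pairs(net)
            gfr = score_gfr(net, pairs, alpha=0.0)
            ra = score_ra(net, pairs)
            for p in pairs:
                assert gfr.score(*p) == pytest.approx(2 * ra.score(*p), abs=1e-12)

    def test_alpha_one_fig4_hand_value(self, fig4):
        # l=3: k=5, |CN(3,2)|=2, |CN(3,1)|=1 -> 1/3 + 1/4
        # l=4: k=4, |CN(4,2)|=1, |CN(4,1)|=1 -> 1/3 + 1/3
        want = (1 / 3 + 1 / 4) + (1 / 3 + 1 / 3)
        assert score_gfr(fig4, [("1", "2")], 1.0).score("1", "2") == pytest.approx(want)

    def test_monotone_nondecreasing_in_alpha(self):
        rng = random.Random(8)
        for _ in range(10):
            net = random_graph(rng)
            pairs = nonadjacent_pairs(net)
            alphas = [0.0, 0.3, 0.7, 1.0]
            tables = [score_gfr(net, pairs, a) for a in alphas]
            for p in pairs:
                vals = [t.score(*p) for t in tables]
                assert all(x <= y + 1e-12 for x, y in zip(vals, vals[1:]))

    def test_alpha_out_of_range_rejected(self, fig4):
        with pytest.raises(ValueError):
            score_gfr(fig4, [("1", "2")], alpha=1.5)


class TestSfr:
    def test_unembedded_common_neighbor_equals_gfr_term(self):
        # single common neighbor sharing nothing with either endpoint:
        # SFR term = 2/k(l) = GFR(1) term
        net = Network([("a", "l"), ("b", "l"), ("l", "x"), ("l", "y")])
        sfr = score_sfr(net, [("a", "b")]).score("a", "b")
        gfr = score_gfr(net, [("a", "b")], 1.0).score("a", "b")
        assert sfr == pytest.approx(2 / 4) == pytest.approx(gfr)

    def test_fig4_hand_value(self, fig4):
        # l=3: 2*5/((5-2)*(5-1)); l=4: 2*4/((4-1)*(4-1))
        want = 10 / 12 + 8 / 9
        assert score_sfr(fig4, [("1", "2")]).score("1", "2") == pytest.approx(want)

    def test_dominates_gfr_at_alpha_one(self):
        rng = random.Random(13)
        checked = 0
        while checked < 500:
            net = random_graph(rng)
            pairs = nonadjacent_pairs(net)
            if not pairs:
                continue
            sfr = score_sfr(net, pairs)
            gfr1 = score_gfr(net, pairs, 1.0)
            gfr0 = score_gfr(net, pairs, 0.0)
            for p in pairs:
                assert sfr.score(*p) >= gfr1.score(*p) - 1e-12
                assert gfr1.score(*p) >= gfr0.score(*p) - 1e-12
            checked += len(pairs)


class TestMfrDispatch:
    def test_significant_regime_delegates_to_sfr(self, planted):
        beta = select_beta(planted)
        census = triple_census(planted, label_ties(planted, beta))
        pairs = nonadjacent_pairs(planted)[:300]
        mfr = score_mfr(planted, pairs, census)
        assert mfr.params["branch"] == "SFR"
        assert mfr.scores == score_sfr(planted, pairs).scores

    def test_weak_regime_delegates_to_fr(self):
        net = gen_erdos_renyi(200, 0.05, seed=0)
        beta = select_beta(net)
        census = triple_census(net, label_ties(net, beta))
        pairs = nonadjacent_pairs(net)[:300]
        mfr = score_mfr(net, pairs, census)
        assert mfr.params["branch"] == "FR"
        assert mfr.scores == score_fr(net, pairs).scores

    def test_non_pwcs_regime_delegates_to_ra(self):
        net = non_pwcs_graph()
        beta = select_beta(net)
        census = triple_census(net, label_ties(net, beta))
        pairs = nonadjacent_pairs(net)[:300]
        mfr = score_mfr(net, pairs, census)
        assert mfr.params["branch"] == "RA"
        assert mfr.scores == score_ra(net, pairs).scores

    def test_undefined_census_propagates(self, fig4):
        census = TripleCensus(beta=0, p1=1.0, p2=None, p3=0.0)
        with pytest.raises(Exception):
            score_mfr(fig4, [("1", "2")], census)


class TestOracleEquivalence:
    @pytest.mark.parametrize("index", ["cn", "aa", "ra", "fr", "gfr", "sfr"])
    def test_matches_brute_force(self, index):
        rng = random.Random(hash(index) % 2**31)
        scorers = {
            "cn": score_cn,
            "aa": score_aa,
            "ra": score_ra,
            "fr": score_fr,
            "sfr": score_sfr,
        }
        for _ in range(25):
            net = random_graph(rng)
            pairs = nonadjacent_pairs(net)
            if index == "gfr":
                alpha = rng.uniform(0, 1)
                table = score_gfr(net, pairs, alpha)
                expect = brute_scores(net.nodes, net.edges, "gfr", alpha=alpha)
            else:
                table = scorers[index](net, pairs)
                expect = brute_scores(net.nodes, net.edges, index)
            for p in pairs:
                assert table.score(*p) == pytest.approx(expect[p], abs=1e-12)


def test_adjacent_pair_is_contract_error_for_fr_family(fig4):
    for scorer in (score_fr, score_sfr):
        with pytest.raises(ValueError):
            scorer(fig4, [("3", "4")])
    with pytest.raises(ValueError):
        score_gfr(fig4, [("3", "4")], 0.5)
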