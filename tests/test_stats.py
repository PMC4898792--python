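import math

import numpy as np
import pytest

import oracle
from conftest import profile_from_newicks, random_profile_newicks
from hybcoal.stats import (
    base_statistics,
    consensus_newick,
    distance_to_consensus,
    greedy_consensus,
    internode_certainty,
    quartet_entropy,
    quartet_resolution_counts,
    rare_splits,
    rf_sum,
    split_incompatibility,
    splits_compatible,
    tree_certainty,
    tree_certainty_all,
    tree_entropy,
    unique_counts,
)


def profile(newicks):
    return profile_from_newicks(newicks)


CAT5 = "((((a,b),c),d),e);"          # caterpillar on 5 taxa
BAL8 = "(((a,b),(c,d)),((e,f),(g,h)));"
CAT8 = "(((((((a,b),c),d),e),f),g),h);"


class TestSplits:
    def test_four_taxon_tree_has_single_split(self):
        p = profile(["((a,b),(c,d));"])
        assert p.tree_splits() == [{0b0011}]

    def test_binary_tree_has_m_minus_3_splits(self):
        p = profile([CAT8])
        assert len(p.tree_splits()[0]) == 5

    def test_caterpillar_splits_by_enumeration(self):
        p = profile([CAT5])
        # ab|cde and abc|de (canonical: smaller-mask side, so abc = 0b00111)
        assert p.tree_splits()[0] == {0b00011, 0b00111}

    @pytest.mark.parametrize(
        "s1,s2,m,expected",
        [
            (0b0011, 0b0011, 4, True),    # self-compatible
            (0b0011, 0b0101, 4, False),   # ab|cd vs ac|bd
            (0b000011, 0b001100, 6, True),  # ab|cdef vs cd|abef: A&B empty
        ],
    )
    def test_compatibility(self, s1, s2, m, expected):
        assert splits_compatible(s1, s2, m) is expected


class TestEntropy:
    def test_identical_trees(self):
        p = profile([CAT5] * 6)
        assert tree_entropy(p) == pytest.approx(6 * math.log(6))
        assert quartet_entropy(p) == pytest.approx(5 * 6 * math.log(6))  # C(5,4)=5

    def test_all_distinct_trees(self):
        p = profile(["((a,b),(c,d));", "((a,c),(b,d));"])
        assert tree_entropy(p) == 0.0
        assert quartet_entropy(p) == 0.0

    def test_te_counts_3_1(self):
        p = profile([CAT5] * 3 + ["(((a,b),(c,d)),e);"])
        assert tree_entropy(p) == pytest.approx(3 * math.log(3))

    def test_te_uses_rooted_identity(self):
        # same unrooted tree, different rootings -> distinct topologies
        p = profile(["((a,b),(c,d));", "(((c,d),b),a);"])
        assert tree_entropy(p) == 0.0

    def test_quartet_weights_sum_to_n(self, rng):
        nwk = random_profile_newicks(6, 7, rng)
        counts = quartet_resolution_counts(profile(nwk))
        assert np.all(counts.sum(axis=1) == 7)


class TestSplitIncompatibility:
    def test_identical_trees_zero(self):
        p = profile([BAL8] * 4)
        for k in (0, 1, 2, 3):
            assert split_incompatibility(p, k) == 0.0

    def test_ordered_pair_convention(self):
        p = profile(["((a,b),(c,d));", "((a,c),(b,d));"])
        assert split_incompatibility(p, 0) == 2.0  # one conflict, both orders
        assert split_incompatibility(p, 1) == 0.0

    def test_monotone_in_threshold(self, rng):
        p = profile(random_profile_newicks(6, 8, rng))
        vals = [split_incompatibility(p, k) for k in range(5)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_rf_sum_differs_from_si_in_general(self):
        # the two printed forms of split incompatibility are not equal: here
        # every split conflicts with every other, inflating the pair form
        p = profile(["((a,b),((c,d),e));", "((a,d),((b,e),c));", "((a,c),((b,d),e));"])
        assert rf_sum(p) != split_incompatibility(p, 0)


class TestConsensusStatistics:
    def test_rare_splits(self):
        assert rare_splits(profile([CAT5])) == 2  # single tree: all weight 1
        assert rare_splits(profile([CAT5] * 3)) == 0
        assert rare_splits(profile(["((a,b),(c,d));", "((a,c),(b,d));"])) == 2

    def test_dc_min_formula(self):
        p = profile(["((a,b),(c,d));"] * 2 + ["((a,c),(b,d));"])
        assert distance_to_consensus(p) == 2  # min(2,1) + min(1,2)

    def test_dc_equals_explicit_consensus_rf(self, rng):
        for _ in range(10):
            nwk = random_profile_newicks(6, 7, rng)
            assert distance_to_consensus(profile(nwk)) == oracle.majority_consensus_rf_sum(nwk)

    def test_unique_counts(self):
        uc, us = unique_counts(profile([BAL8] * 3))
        assert (uc, us) == (4, 5)
        uc, us = unique_counts(profile([CAT8] * 3))
        assert (uc, us) == (2, 5)

    def test_greedy_consensus_prefers_heavier_split(self):
        p = profile(["((a,b),(c,d));"] * 2 + ["((a,c),(b,d));"])
        assert greedy_consensus(p) == [0b0011]

    def test_greedy_consensus_contains_majority_and_is_compatible(self, rng):
        for _ in range(5):
            p = profile(random_profile_newicks(6, 8, rng))
            accepted = greedy_consensus(p)
            w = p.split_weights()
            for s in w:
                if w[s] > p.n / 2:
                    assert s in accepted
            for i, s in enumerate(accepted):
                for t in accepted[i + 1:]:
                    assert splits_compatible(s, t, p.m)

    def test_consensus_newick_roundtrip(self):
        p = profile([BAL8] * 3)
        nwk = consensus_newick(greedy_consensus(p), p.taxa)
        assert profile([nwk]).tree_splits()[0] == set(greedy_consensus(p))


class TestCertainty:
    @pytest.mark.parametrize(
        "x1,x2,expected",
        [(5, 0, 1.0), (3, 3, 0.0), (3, 1, 0.18872187554086717)],
    )
    def test_internode_certainty_closed_form(self, x1, x2, expected):
        assert internode_certainty(x1, x2) == pytest.approx(expected)

    def test_unanimous_profile_maxes_certainty(self):
        p = profile([BAL8] * 5)
        assert tree_certainty(p) == pytest.approx(5.0)       # m - 3
        assert tree_certainty_all(p) == pytest.approx(5.0)

    def test_single_conflict_tc(self):
        p = profile(["((a,b),(c,d));"] * 3 + ["((a,c),(b,d));"])
        assert tree_certainty(p) == pytest.approx(internode_certainty(3, 1))
        # one conflicting split: ICA degenerates to IC
        assert tree_certainty_all(p) == pytest.approx(tree_certainty(p))


class TestFullVectorAgainstOracle:
    def test_identical_tree_profile_vector(self):
        p = profile([BAL8] * 4)
        v = base_statistics(p)
        assert v["TE"] == pytest.approx(4 * math.log(4))
        assert v["QE"] == pytest.approx(70 * 4 * math.log(4))
        assert (v["SI"], v["SI1"], v["SI2"], v["RS"], v["DC"]) == (0, 0, 0, 0, 0)
        assert (v["UC"], v["US"]) == (4, 5)
        assert v["TC"] == v["TCA"] == pytest.approx(5.0)

    @pytest.mark.parametrize("m,n,seed", [(4, 6, 1), (5, 8, 2), (6, 8, 3), (6, 5, 4)])
    def test_matches_bruteforce_oracle(self, m, n, seed):
        rng = np.random.default_rng(seed)
        for _ in range(13):
            nwk = random_profile_newicks(m, n, rng)
            got = base_statistics(profile(nwk))
            want = oracle.base_statistics(nwk)
            for key in want:
                assert got[key] == pytest.approx(want[key], abs=1e-9), (key, nwk)
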