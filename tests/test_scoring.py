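import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isopair.datasets import ExpressionDataset
from isopair.scoring import (
    PairScorer,
    information_gain,
    rank_pairs,
    rules_from_ranking,
    score_s1,
    score_s2,
)

from conftest import make_dataset, random_instance
from oracles import oracle_rank_pairs, oracle_s1, oracle_s2


LBL = ["normal"] * 4 + ["tumor"] * 4


class TestScoreS1:
    def test_perfect_reversal(self):
        x_i = [3, 3, 3, 3, 1, 1, 1, 1]
        x_j = [1, 1, 1, 1, 3, 3, 3, 3]
        assert score_s1(x_i, x_j, LBL, "normal", "tumor") == 1.0

    def test_constant_order_scores_zero(self):
        x_i = [3] * 8
        x_j = [1] * 8
        assert score_s1(x_i, x_j, LBL, "normal", "tumor") == 0.0

    def test_tie_counts_in_denominator_only(self):
        # C1: i > j in 3 of 4; C2: i < j in 3 of 4 with one exact tie
        x_i = [3, 3, 3, 0, 1, 1, 1, 2]
        x_j = [1, 1, 1, 2, 3, 3, 3, 2]
        assert score_s1(x_i, x_j, LBL, "normal", "tumor") == pytest.approx(0.5)

    def test_half_policy_splits_ties(self):
        x_i = [2, 2, 1, 1]
        x_j = [2, 2, 3, 3]
        labels = ["normal", "normal", "tumor", "tumor"]
        assert score_s1(x_i, x_j, labels, "normal", "tumor", "strict") == 0.0
        assert score_s1(x_i, x_j, labels, "normal", "tumor", "half") == 0.5

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            score_s1([1, 2], [1], ["normal", "tumor"], "normal", "tumor")

    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_orientation_class_swap_symmetry_without_ties(self, data):
        n = data.draw(st.integers(4, 10))
        n1 = data.draw(st.integers(1, n - 1))
        labels = ["A"] * n1 + ["B"] * (n - n1)
        # distinct values => no ties
        vals = data.draw(st.permutations(range(2 * n)))
        x_i, x_j = list(vals[:n]), list(vals[n:])
        s = score_s1(x_i, x_j, labels, "A", "B")
        s_swapped = score_s1(x_j, x_i, labels, "B", "A")
        # swapping both orientation and class roles leaves S1 unchanged
        assert s == pytest.approx(s_swapped)
        assert -1.0 <= s <= 1.0

    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_invariant_under_monotone_per_sample_transform(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        x_i = rng.integers(0, 5, 8).astype(float)
        x_j = rng.integers(0, 5, 8).astype(float)
        s = score_s1(x_i, x_j, LBL, "normal", "tumor")
        # strictly monotone transform (different per sample)
        a = rng.uniform(0.5, 2.0, 8)
        b = rng.uniform(0, 3, 8)
        assert score_s1(a * x_i + b, a * x_j + b, LBL, "normal", "tumor") == s


class TestScoreS2:
    def test_no_rank_shift_is_zero(self):
        ranks = np.array([[2.0] * 8, [5.0] * 8])
        assert score_s2(None, None, LBL, "normal", "tumor", sample_ranks=ranks) == 0.0

    def test_known_rank_differences(self):
        # C1 rank differences (+2, +2), C2 (-2, -2)
        ranks = np.array([[3, 3, 1, 1], [1, 1, 3, 3]], dtype=float)
        labels = ["normal", "normal", "tumor", "tumor"]
        assert score_s2(None, None, labels, "normal", "tumor", sample_ranks=ranks) == 4.0

    def test_matches_bruteforce_on_random_instance(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 10, size=(6, 8)).astype(float)
        from scipy.stats import rankdata

        ranks = rankdata(x, axis=0, method="average")
        got = score_s2(None, None, LBL, "normal", "tumor", sample_ranks=ranks[[2, 4]])
        assert got == pytest.approx(oracle_s2(ranks[2], ranks[4], LBL, "normal", "tumor"))


class TestInformationGain:
    def _ds(self, x_t, x_n):
        matrix = {"g.t": list(map(float, x_t)), "g.n": list(map(float, x_n))}
        return make_dataset(matrix, {"g.t": "g", "g.n": "g"}, LBL)

    def _rule(self, ds):
        return rules_from_ranking(rank_pairs(ds))[0]

    def test_perfect_rule_on_balanced_set_is_one_bit(self):
        ds = self._ds([1, 1, 1, 1, 3, 3, 3, 3], [3, 3, 3, 3, 1, 1, 1, 1])
        assert information_gain(self._rule(ds), ds) == pytest.approx(1.0)

    def test_constant_vote_carries_no_information(self):
        ds = self._ds([3] * 8, [1] * 8)
        assert information_gain(self._rule(ds), ds) == pytest.approx(0.0)

    def test_derived_entropy_value(self):
        # balanced 4+4, rule correct on 3 C1 and all 4 C2:
        # IG = 1 - (5/8)*H(1/5, 4/5) ~ 0.5488
        ds = self._ds([1, 1, 1, 3, 3, 3, 3, 3], [3, 3, 3, 1, 1, 1, 1, 1])
        h15 = -(1 / 5) * np.log2(1 / 5) - (4 / 5) * np.log2(4 / 5)
        expected = 1 - (5 / 8) * h15
        assert expected == pytest.approx(0.54879494, abs=1e-6)
        assert information_gain(self._rule(ds), ds) == pytest.approx(expected)


class TestRankPairs:
    def test_single_perfect_pair(self, perfect_dataset):
        ranking = rank_pairs(perfect_dataset)
        top = ranking.iloc[0]
        assert top["gene"] == "ga"
        assert top["s1"] == 1.0
        assert top["rank"] == 1
        assert top["tumor_isoform"] == "ga.t1"
        assert top["normal_isoform"] == "ga.t2"

    def test_per_gene_best_only(self):
        matrix = {
            "g.a": [1, 1, 9, 9],  # perfect reversal with g.b
            "g.b": [9, 9, 1, 1],
            "g.c": [5, 4, 5, 4],  # weaker against either
        }
        ds = make_dataset(matrix, {t: "g" for t in matrix}, ["normal"] * 2 + ["tumor"] * 2)
        ranking = rank_pairs(ds)
        assert len(ranking) == 1
        assert {ranking.iloc[0]["tumor_isoform"], ranking.iloc[0]["normal_isoform"]} == {
            "g.a", "g.b"
        }
        assert ranking.iloc[0]["s1"] == 1.0

    @pytest.mark.parametrize("tie_policy", ["strict", "half"])
    def test_matches_bruteforce_oracle(self, tie_policy):
        rng = np.random.default_rng(11)
        for _ in range(60):
            expression, gene_of, labels = random_instance(rng)
            ds = make_dataset(expression, gene_of, labels)
            got = rank_pairs(ds, tie_policy=tie_policy)
            exp = oracle_rank_pairs(
                expression, gene_of, labels, "normal", "tumor", tie_policy
            )
            assert len(got) == len(exp)
            for grow, erow in zip(got.itertuples(index=False), exp):
                assert grow.gene == erow["gene"]
                assert grow.tumor_isoform == erow["tumor_isoform"]
                assert grow.normal_isoform == erow["normal_isoform"]
                assert grow.s1 == erow["s1"]
                assert grow.s2 == erow["s2"]
                assert grow.ig == pytest.approx(erow["ig"], abs=1e-12)

    def test_degenerate_pairs_excluded_and_flagged(self):
        matrix = {"g.a": [2.0, 2.0, 2.0, 2.0], "g.b": [2.0, 2.0, 2.0, 2.0]}
        ds = make_dataset(matrix, {t: "g" for t in matrix}, ["normal"] * 2 + ["tumor"] * 2)
        scorer = PairScorer(ds)
        assert scorer.all_degenerate
        assert len(scorer.ranking()) == 0

    def test_listed_pairs_nonnegative_s1(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            expression, gene_of, labels = random_instance(rng)
            ranking = rank_pairs(make_dataset(expression, gene_of, labels))
            assert (ranking["s1"] >= 0).all()
            assert (ranking["s1"] <= 1).all()
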