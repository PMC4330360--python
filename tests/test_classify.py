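import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isopair.classify import (
    ConfusionCounts,
    PairClassifier,
    accuracy,
    blind_test,
    classifier_from_ranking,
    evaluate_rule,
    gene_level_dataset,
    rank_gene_pairs,
)
from isopair.scoring import IsoformPairRule, rank_pairs

from conftest import make_dataset
from oracles import oracle_s1


def _rule(gene="g", t="g.t", n="g.n", rank=1):
    return IsoformPairRule(gene=gene, tumor_isoform=t, normal_isoform=n,
                           s1=1.0, s2=0.0, ig=1.0, rank=rank)


class TestEvaluateRule:
    def test_lower_tumor_isoform_votes_normal(self):
        assert evaluate_rule(_rule(), {"g.t": 2, "g.n": 5}, "normal", "tumor") == "normal"

    def test_higher_tumor_isoform_votes_tumor(self):
        assert evaluate_rule(_rule(), {"g.t": 5, "g.n": 2}, "normal", "tumor") == "tumor"

    def test_tie_takes_else_branch(self):
        assert evaluate_rule(_rule(), {"g.t": 0, "g.n": 0}, "normal", "tumor") == "tumor"

    def test_configurable_tie_vote(self):
        assert (
            evaluate_rule(_rule(), {"g.t": 1, "g.n": 1}, "normal", "tumor", tie_vote="class1")
            == "normal"
        )

    def test_missing_isoform_raises(self):
        with pytest.raises(KeyError, match="g.n"):
            evaluate_rule(_rule(), {"g.t": 1}, "normal", "tumor")


class TestMajorityVoting:
    def _model(self, k):
        rules = [_rule(gene=f"g{i}", t=f"g{i}.t", n=f"g{i}.n", rank=i + 1) for i in range(k)]
        return PairClassifier(rules, "normal", "tumor")

    def test_two_tumor_one_normal_votes_classify_tumor(self):
        # the k=3 worked example: votes (tumor, tumor, normal) -> tumor
        model = self._model(3)
        expr = {"g0.t": 5, "g0.n": 1, "g1.t": 5, "g1.n": 1, "g2.t": 1, "g2.n": 5}
        assert model.classify_sample(expr) == ("tumor", 2)

    def test_k1_follows_single_rule(self):
        model = self._model(1)
        assert model.classify_sample({"g0.t": 1, "g0.n": 5}) == ("normal", 1)

    def test_unanimous_k5(self):
        model = self._model(5)
        expr = {f"g{i}.{x}": (5 if x == "t" else 1) for i in range(5) for x in "tn"}
        assert model.classify_sample(expr) == ("tumor", 5)

    def test_even_k_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            self._model(2)

    def test_duplicate_gene_rejected(self):
        rules = [_rule(), _rule(), _rule()]
        with pytest.raises(ValueError, match="distinct genes"):
            PairClassifier(rules, "normal", "tumor")

    @given(st.integers(1, 4), st.integers(0, 10**6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_odd_k_never_ties_and_winner_majority(self, half_k, seed):
        k = 2 * half_k + 1
        model = self._model(k)
        rng = np.random.default_rng(seed)
        expr = {}
        for i in range(k):
            t, n = rng.integers(0, 5, 2)
            expr[f"g{i}.t"], expr[f"g{i}.n"] = float(t), float(n)
        cls, votes = model.classify_sample(expr)
        assert votes > k / 2

    def test_classification_invariant_under_monotone_transform(self):
        model = self._model(3)
        rng = np.random.default_rng(4)
        expr = {f"g{i}.{x}": float(v) for i, x, v in
                [(i, x, rng.integers(0, 9)) for i in range(3) for x in "tn"]}
        before = model.classify_sample(expr)
        after = model.classify_sample({k: 3 * v + 1 for k, v in expr.items()})
        assert before == after


class TestAccuracy:
    def test_example(self):
        assert accuracy(ConfusionCounts(tp=3, tn=4, fp=0, fn=1)) == 0.875

    def test_all_correct(self):
        assert accuracy(ConfusionCounts(tp=2, tn=2, fp=0, fn=0)) == 1.0

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionCounts(0, 0, 0, 0))

    @given(st.tuples(*[st.integers(0, 50)] * 4))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetric_in_class_designation(self, counts):
        tp, tn, fp, fn = counts
        if tp + tn + fp + fn == 0:
            return
        c = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
        assert accuracy(c) == accuracy(c.swapped())


class TestBlindTest:
    def _fit(self, ds, k):
        return classifier_from_ranking(rank_pairs(ds), k, ds.class1, ds.class2)

    def test_all_rules_fulfilled(self, perfect_dataset):
        model = self._fit(perfect_dataset, 1)
        tumor_like = pd.DataFrame({"b1": [9.0, 1.0, 6.0, 2.0]},
                                  index=["ga.t1", "ga.t2", "gb.t1", "gb.t2"])
        frac, hist = blind_test(model, tumor_like, "tumor")
        assert frac == 1.0
        assert hist[1] == 1

    def test_minority_fulfilment_counts_incorrect(self):
        rules = [_rule(gene=f"g{i}", t=f"g{i}.t", n=f"g{i}.n") for i in range(3)]
        model = PairClassifier(rules, "normal", "tumor")
        # sample fulfils only rule 0 for tumor
        expr = pd.DataFrame(
            {"s": [5, 1, 1, 5, 1, 5]},
            index=["g0.t", "g0.n", "g1.t", "g1.n", "g2.t", "g2.n"],
        )
        frac, hist = blind_test(model, expr, "tumor")
        assert frac == 0.0
        assert hist[1] == 1

    def test_matches_per_sample_oracle_on_synthetic(self, small_sim):
        ds, *_ = small_sim
        model = self._fit(ds, 3)
        unpaired = [s for s in ds.sample_ids if s.startswith("U")]
        frac, hist = blind_test(model, ds.abundance[unpaired], "tumor")
        # direct per-sample oracle
        correct = 0
        for s in unpaired:
            n_for = sum(
                ds.abundance.loc[r.tumor_isoform, s] >= ds.abundance.loc[r.normal_isoform, s]
                for r in model.rules
            )
            correct += n_for >= 2
        assert frac == correct / len(unpaired)
        assert hist.sum() == len(unpaired)


class TestGeneLevelMode:
    def test_gene_tpm_is_sum_of_isoforms(self):
        matrix = {"g.a": [30.0, 1.0], "g.b": [10.0, 2.0], "h.a": [7.0, 7.0]}
        ds = make_dataset(matrix, {"g.a": "g", "g.b": "g", "h.a": "h"}, ["normal", "tumor"])
        gl = gene_level_dataset(ds)
        assert gl.abundance.loc["g"].tolist() == [40.0, 3.0]
        assert gl.abundance.loc["h"].tolist() == [7.0, 7.0]  # single isoform passes through

    def test_matches_bruteforce_ktsp_on_tiny_instance(self):
        rng = np.random.default_rng(9)
        matrix = {}
        gene_of = {}
        for g in "abcd":
            for t in range(2):
                tid = f"{g}.t{t}"
                matrix[tid] = list(rng.integers(0, 20, 6).astype(float))
                gene_of[tid] = g
        labels = ["normal"] * 3 + ["tumor"] * 3
        ds = make_dataset(matrix, gene_of, labels)
        ranking = rank_gene_pairs(ds)

        # oracle: score all gene pairs on summed expression, sort, greedy disjoint
        sums = {g: [sum(matrix[f"{g}.t{t}"][i] for t in range(2)) for i in range(6)]
                for g in "abcd"}
        cands = []
        for gi in "abcd":
            for gj in "abcd":
                if gi >= gj:
                    continue
                s_ab = oracle_s1(sums[gi], sums[gj], labels, "normal", "tumor")
                s_ba = oracle_s1(sums[gj], sums[gi], labels, "normal", "tumor")
                if s_ab >= s_ba:
                    normal, tumor, s1 = gi, gj, s_ab
                else:
                    normal, tumor, s1 = gj, gi, s_ba
                if s1 >= 0:
                    cands.append((s1, tumor, normal))
        cands.sort(key=lambda c: (-c[0], c[1], c[2]))
        assert len(ranking) >= 1
        top = ranking.iloc[0]
        assert top["s1"] == max(c[0] for c in cands)
        # disjointness: each gene at most once
        used = list(ranking["tumor_feature"]) + list(ranking["normal_feature"])
        assert len(used) == len(set(used))
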