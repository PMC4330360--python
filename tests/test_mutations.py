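import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from isopair.datasets import MutationTable, TranscriptStructure
from isopair.mutations import (
    background_zscore,
    delta_psi_mutation_test,
    jaccard_association,
    mutated_samples,
    mutual_exclusion,
    mutual_information_association,
    select_background_genes,
)

from conftest import make_dataset


def _structures():
    return {
        "g.t": TranscriptStructure("g.t", "chr1", "+", [(100, 200), (400, 500)]),
        "g.n": TranscriptStructure("g.n", "chr1", "+", [(100, 200), (900, 1000)]),
    }


def _mut(sample, start, end=None, mclass="missense", chrom="chr1"):
    return {"sample": sample, "chrom": chrom, "start": start,
            "end": end or start, "mut_class": mclass, "gene": "g"}


class TestMutatedSamples:
    def test_exonic_hit_included(self):
        muts = MutationTable(pd.DataFrame([_mut("s1", 150)]))
        got = mutated_samples(["g.t", "g.n"], muts, _structures())
        assert got == {"s1"}

    def test_distant_mutation_excluded(self):
        muts = MutationTable(pd.DataFrame([_mut("s1", 12000)]))
        assert mutated_samples(["g.t", "g.n"], muts, _structures()) == set()

    def test_gene_scope_catches_inter_transcript_gap(self):
        # position 700: outside both transcript spans' union? g.t span 100-500,
        # g.n span 100-1000 -> inside g.n span; use 501..899 gap with narrower n
        structs = {
            "g.t": TranscriptStructure("g.t", "chr1", "+", [(100, 200)]),
            "g.n": TranscriptStructure("g.n", "chr1", "+", [(900, 1000)]),
        }
        muts = MutationTable(pd.DataFrame([_mut("s1", 500)]))
        assert mutated_samples(["g.t", "g.n"], muts, structs, scope="transcript") == set()
        assert mutated_samples(["g.t", "g.n"], muts, structs, scope="gene") == {"s1"}

    def test_protein_affecting_filter(self):
        muts = MutationTable(pd.DataFrame([
            _mut("s1", 150, mclass="synonymous"), _mut("s2", 150, mclass="nonsense"),
        ]))
        got = mutated_samples(["g.t", "g.n"], muts, _structures(),
                              protein_affecting_only=True)
        assert got == {"s2"}

    def test_missing_structure_errors(self):
        muts = MutationTable(pd.DataFrame([_mut("s1", 150)]))
        with pytest.raises(KeyError, match="g.x"):
            mutated_samples(["g.t", "g.x"], muts, _structures())

    def test_closed_interval_boundaries(self):
        muts = MutationTable(pd.DataFrame([_mut("s1", 500), _mut("s2", 501)]))
        structs = {"g.t": TranscriptStructure("g.t", "chr1", "+", [(100, 500)])}
        assert mutated_samples(["g.t"], muts, structs) == {"s1"}


class TestJaccard:
    def test_identical_sets(self):
        assert jaccard_association({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets(self):
        assert jaccard_association({"a"}, {"b"}) == 0.0

    def test_fraction(self):
        S = {"a", "b", "c", "d", "e"}
        M = {"d", "e", "f", "g", "h"}
        assert jaccard_association(S, M) == 0.25

    def test_empty_union(self):
        assert jaccard_association(set(), set()) == 0.0


class TestMutualInformation:
    def test_exact_product_table_is_zero(self):
        # N=8: S covers 4, M covers 4, overlap 2 => independent
        S = {f"s{i}" for i in range(4)}
        M = {"s0", "s1", "s4", "s5"}
        assert mutual_information_association(S, M, 8) == pytest.approx(0.0, abs=1e-12)

    def test_identical_half_coverage_is_one_bit(self):
        S = {f"s{i}" for i in range(5)}
        assert mutual_information_association(S, S, 10) == pytest.approx(1.0)

    def test_matches_plugin_formula_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            N = int(rng.integers(4, 30))
            samples = [f"s{i}" for i in range(N)]
            S = {s for s in samples if rng.random() < 0.4}
            M = {s for s in samples if rng.random() < 0.3}
            got = mutual_information_association(S, M, N)
            # independent plug-in oracle over the 2x2 table
            mi = 0.0
            for in_s in (True, False):
                for in_m in (True, False):
                    p = sum(((x in S) == in_s) and ((x in M) == in_m) for x in samples) / N
                    ps = len(S) / N if in_s else 1 - len(S) / N
                    pm = len(M) / N if in_m else 1 - len(M) / N
                    if p > 0:
                        mi += p * math.log2(p / (ps * pm))
            assert got == pytest.approx(max(mi, 0.0), abs=1e-12)
            assert got >= 0


class TestMutualExclusion:
    @pytest.mark.parametrize("n10,n01,N,expected", [
        (5, 5, 10, 1.0),
        (4, 0, 10, 0.0),
        (3, 1, 10, 0.2),
    ])
    def test_formula(self, n10, n01, N, expected):
        assert mutual_exclusion(n10, n01, N) == expected

    def test_exhaustive_small_tables(self):
        for N in range(1, 9):
            for n10 in range(N + 1):
                for n01 in range(N - n10 + 1):
                    mx = mutual_exclusion(n10, n01, N)
                    assert mx == 2 * min(n10, n01) / N
                    assert 0.0 <= mx <= 1.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            mutual_exclusion(6, 6, 10)


class TestBackgroundZscore:
    def test_simple_value(self):
        bg = [0.1, 0.05, 0.15]  # mean 0.1, population sd ~0.0408
        z = background_zscore(0.3, bg)
        assert z == pytest.approx((0.3 - 0.1) / np.std(bg))

    def test_observed_at_mean_is_zero(self):
        assert background_zscore(0.1, [0.05, 0.15]) == 0.0

    def test_constant_background_flagged_missing(self):
        with pytest.warns(UserWarning, match="constant background"):
            assert background_zscore(0.3, [0.1, 0.1, 0.1]) is None

    def test_nearest_length_selection_deterministic(self):
        structs = {}
        transcripts_of = {}
        for i, ln in enumerate([100, 200, 300, 400, 500, 500]):
            g = f"g{i}"
            ts = [f"{g}.a", f"{g}.b"]
            transcripts_of[g] = ts
            for t in ts:
                structs[t] = TranscriptStructure(t, "chr1", "+", [(1, ln)])
        got = select_background_genes("g2", transcripts_of, structs, n_background=3)
        # distances from 300: g1=100, g3=100, then g0/g4/g5 all at 200 (tie
        # broken by gene id, so g0 enters first)
        assert got == ["g1", "g3", "g0"]
        assert got == select_background_genes("g2", transcripts_of, structs, 3)


class TestDeltaPsiTest:
    def _dataset(self, psi_t_tumor):
        # 2-isoform gene, tumor samples only matter; PSI_t as given
        n = len(psi_t_tumor)
        t_vals = [50.0] * 2 + [100 * p for p in psi_t_tumor]
        n_vals = [50.0] * 2 + [100 * (1 - p) for p in psi_t_tumor]
        matrix = {"g.t": t_vals, "g.n": n_vals}
        labels = ["normal"] * 2 + ["tumor"] * n
        return make_dataset(matrix, {"g.t": "g", "g.n": "g"}, labels)

    def test_complete_separation_3v3_exact(self):
        # exact two-sided Mann-Whitney for 3 vs 3 with full separation: p = 0.1
        ds = self._dataset([0.9, 0.8, 0.85, 0.2, 0.1, 0.15])
        tumor = [s for s in ds.sample_ids if ds.class_of[s] == "tumor"]
        p = delta_psi_mutation_test("g.t", "g.n", ds, set(tumor[:3]), tumor)
        assert p == pytest.approx(0.1)

    def test_all_tied_gives_p_one(self):
        ds = self._dataset([0.5] * 6)
        tumor = [s for s in ds.sample_ids if ds.class_of[s] == "tumor"]
        assert delta_psi_mutation_test("g.t", "g.n", ds, set(tumor[:3]), tumor) == 1.0

    def test_empty_group_flagged(self):
        ds = self._dataset([0.5, 0.6, 0.7])
        tumor = [s for s in ds.sample_ids if ds.class_of[s] == "tumor"]
        with pytest.warns(UserWarning, match="empty"):
            assert delta_psi_mutation_test("g.t", "g.n", ds, set(), tumor) is None

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(150):
            psis = rng.uniform(0.2, 0.8, 24)
            ds = self._dataset(list(psis))
            tumor = [s for s in ds.sample_ids if ds.class_of[s] == "tumor"]
            mutated = set(rng.choice(tumor, size=12, replace=False))
            pvals.append(delta_psi_mutation_test("g.t", "g.n", ds, mutated, tumor))
        # discrete two-sided rank-test p-values are slightly conservative;
        # require no anti-conservatism rather than exact uniformity
        assert kstest(pvals, "uniform", alternative="greater").pvalue > 0.01

    def test_shifted_distributions_detected(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(20):
            base = rng.uniform(0.15, 0.35, 20)
            shifted = np.clip(base[:10] + 0.5, 0, 1)
            psis = list(shifted) + list(base[10:])
            ds = self._dataset(psis)
            tumor = [s for s in ds.sample_ids if ds.class_of[s] == "tumor"]
            p = delta_psi_mutation_test("g.t", "g.n", ds, set(tumor[:10]), tumor)
            hits += p < 0.05
        assert hits >= 18  # power >= 90%
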