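"""Reversal scores for isoform pairs and the one-pair-per-gene ranking.

For two isoforms i, j of the same gene and samples split into classes C1
(normal-like) and C2 (tumor-like), the primary score is

    S1(i, j) = P(x_i > x_j | C1) + P(x_i < x_j | C2) - 1,

the sum of the within-class frequencies of the two opposite relative
expression orders.  S1 = 1 means a perfect reversal: i above j in every C1
sample and below j in every C2 sample.  Because RNA-seq yields many exact
ties (in particular double zeros), the frequencies use *strict* inequalities
by default: tied samples count in neither numerator but remain in the
denominator, so unexpressed pairs are penalised rather than rewarded.  The
alternative "half" policy splits each tie 0.5/0.5 between the two orders.

S1 ties in the ranking are broken by S2, the absolute between-class
difference of the mean within-sample rank difference of the two isoforms
(ranks taken across all transcripts of a sample, average ranks for ties).
Each listed pair also carries its information gain (IG): the reduction, in
bits, of the class entropy achieved by the single pair-rule's vote.

Orientation: for the maximising argument order (i, j) of S1, i is the
isoform that sits higher in C1 — the *normal* isoform — and j the *tumor*
isoform.  Rules are reported as (tumor_isoform, normal_isoform) with the
semantics "tumor_isoform < normal_isoform => class1, else class2".

Only one pair per gene is listed (the gene's best by S1 then S2); pairs that
are tied in every evaluated sample are degenerate (S1 = -1 under the strict
policy) and excluded, as are pairs whose best orientation still has S1 < 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datasets import ExpressionDataset

__all__ = [
    "IsoformPairRule",
    "PairScorer",
    "score_s1",
    "score_s2",
    "information_gain",
    "rank_pairs",
    "sample_rankings",
]

_LOG2 = np.log(2.0)


@dataclass(frozen=True)
class IsoformPairRule:
    """One oriented isoform-pair rule: tumor_isoform < normal_isoform => class1."""

    gene: str
    tumor_isoform: str
    normal_isoform: str
    s1: float
    s2: float
    ig: float
    rank: int


def _class_masks(labels, class1: str, class2: str) -> tuple[np.ndarray, np.ndarray]:
    lab = np.asarray(labels)
    m1 = lab == class1
    m2 = lab == class2
    if not m1.any() or not m2.any():
        raise ValueError("each class needs at least one sample")
    if not (m1 | m2).all():
        raise ValueError("labels contain values other than the two classes")
    return m1, m2


def score_s1(x_i, x_j, labels, class1, class2, tie_policy: str = "strict") -> float:
    """S1 = P(x_i > x_j | C1) + P(x_i < x_j | C2) - 1.

    Frequencies are computed over all samples of each class.  Under the
    default strict policy, tied samples (including double zeros) count in
    the denominator only.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape or len(x_i) != len(labels):
        raise ValueError("expression vectors and labels must have equal length")
    m1, m2 = _class_masks(labels, class1, class2)
    gt = (x_i > x_j).astype(float)
    lt = (x_i < x_j).astype(float)
    if tie_policy == "half":
        tie = 1.0 - gt - lt
        gt = gt + 0.5 * tie
        lt = lt + 0.5 * tie
    elif tie_policy != "strict":
        raise ValueError("tie_policy must be 'strict' or 'half'")
    return float(gt[m1].mean() + lt[m2].mean() - 1.0)


def sample_rankings(x: np.ndarray) -> np.ndarray:
    """Within-sample ranks across all transcripts (rank 1 = lowest, ties averaged)."""
    return rankdata(x, axis=0, method="average")


def score_s2(x_i, x_j, labels, class1, class2, sample_ranks=None) -> float:
    """|mean_{C1}(r_i - r_j) - mean_{C2}(r_i - r_j)| with within-sample ranks.

    ``sample_ranks`` is the (i, j)-row pair of the full within-sample ranking
    matrix; without a surrounding transcriptome the two vectors are ranked
    against each other alone.
    """
    if sample_ranks is None:
        sample_ranks = sample_rankings(np.vstack([x_i, x_j]))
    r_i, r_j = np.asarray(sample_ranks, dtype=float)
    if len(r_i) != len(labels):
        raise ValueError("rank vectors and labels must have equal length")
    m1, m2 = _class_masks(labels, class1, class2)
    d = r_i - r_j
    return float(abs(d[m1].mean() - d[m2].mean()))


def _entropy_bits(p: np.ndarray) -> np.ndarray:
    """Elementwise -p*log2(p) with 0*log0 := 0."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = -p[pos] * np.log(p[pos]) / _LOG2
    return out


def _ig_from_counts(c1_t, c2_t, n1: float, n2: float):
    """IG (bits) from per-pair counts of C1/C2 samples voting class2 ("tumor")."""
    c1_t = np.asarray(c1_t, dtype=float)
    c2_t = np.asarray(c2_t, dtype=float)
    n = n1 + n2
    h_class = (_entropy_bits(np.array(n1 / n)) + _entropy_bits(np.array(n2 / n))).item()
    nt = c1_t + c2_t
    nn = n - nt
    with np.errstate(invalid="ignore", divide="ignore"):
        pt = np.where(nt > 0, c1_t / np.where(nt > 0, nt, 1.0), 0.0)
        pn = np.where(nn > 0, (n1 - c1_t) / np.where(nn > 0, nn, 1.0), 0.0)
    h_t = _entropy_bits(pt) + _entropy_bits(1.0 - pt)
    h_n = _entropy_bits(pn) + _entropy_bits(1.0 - pn)
    h_cond = (nt / n) * np.where(nt > 0, h_t, 0.0) + (nn / n) * np.where(nn > 0, h_n, 0.0)
    return h_class - h_cond


def information_gain(rule, dataset: ExpressionDataset) -> float:
    """IG in bits of a single pair-rule's vote over the dataset's samples.

    The vote is class2 ("tumor") whenever expression(tumor_isoform) >=
    expression(normal_isoform), i.e. ties take the rule's "else" branch.
    """
    t = np.asarray(dataset.abundance.loc[rule.tumor_isoform], dtype=float)
    n = np.asarray(dataset.abundance.loc[rule.normal_isoform], dtype=float)
    labels = dataset.class_of[dataset.sample_ids].to_numpy()
    m1, m2 = _class_masks(labels, dataset.class1, dataset.class2)
    vote_t = t >= n
    return float(
        _ig_from_counts(
            np.array([vote_t[m1].sum()]),
            np.array([vote_t[m2].sum()]),
            m1.sum(),
            m2.sum(),
        )[0]
    )


class PairScorer:
    """Vectorised scorer for all same-gene isoform pairs of a dataset.

    The per-sample order comparisons between the two members of every pair
    are label-independent, so they are precomputed once; scoring a labelling
    (the training labels, a cross-validation fold, or a permutation) then
    reduces to a handful of matrix-vector products.  This is what makes
    1000-permutation nulls and leave-one-pair-out folds cheap.
    """

    def __init__(self, dataset: ExpressionDataset, tie_policy: str = "strict") -> None:
        if tie_policy not in ("strict", "half"):
            raise ValueError("tie_policy must be 'strict' or 'half'")
        self.dataset = dataset
        self.tie_policy = tie_policy
        self.labels = dataset.class_of[dataset.sample_ids].to_numpy()

        x = dataset.abundance.to_numpy(dtype=float)
        genes = dataset.gene_of[dataset.transcript_ids].to_numpy()
        order = np.argsort(genes, kind="stable")
        ia, ib, gene_codes, gene_names = [], [], [], []
        code = -1
        start = 0
        while start < len(order):
            stop = start
            g = genes[order[start]]
            while stop < len(order) and genes[order[stop]] == g:
                stop += 1
            idx = order[start:stop]
            if stop - start >= 2:
                code += 1
                gene_names.append(g)
                for a in range(len(idx)):
                    for b in range(a + 1, len(idx)):
                        ia.append(idx[a])
                        ib.append(idx[b])
                        gene_codes.append(code)
            start = stop
        self.pair_a = np.asarray(ia, dtype=np.intp)
        self.pair_b = np.asarray(ib, dtype=np.intp)
        self.pair_gene = np.asarray(gene_codes, dtype=np.intp)
        self.gene_names = np.asarray(gene_names, dtype=object)
        self.n_pairs = len(self.pair_a)

        xa = x[self.pair_a]
        xb = x[self.pair_b]
        self._gt = (xa > xb).astype(np.float64)  # pair x sample: a above b
        self._lt = (xa < xb).astype(np.float64)
        ranks = sample_rankings(x)
        self._rd = ranks[self.pair_a] - ranks[self.pair_b]
        self._tids = np.asarray(dataset.transcript_ids, dtype=object)

    # -- core labelling evaluation ----------------------------------------

    def _masks_from_labels(self, labels) -> tuple[np.ndarray, np.ndarray]:
        return _class_masks(labels, self.dataset.class1, self.dataset.class2)

    def score_labels(self, labels=None, sample_mask=None):
        """Score every pair under a labelling; return per-pair arrays.

        Returns a dict with oriented ``s1``, ``s2``, boolean ``rev`` (True
        when the *first* transcript of the stored pair is the tumor isoform),
        and ``degenerate`` (pair tied in every evaluated sample).
        """
        labels = self.labels if labels is None else np.asarray(labels)
        m1, m2 = self._masks_from_labels(labels)
        if sample_mask is not None:
            m1 = m1 & sample_mask
            m2 = m2 & sample_mask
            if not m1.any() or not m2.any():
                raise ValueError("sample mask removes an entire class")
        w1 = m1.astype(float)
        w2 = m2.astype(float)
        n1 = w1.sum()
        n2 = w2.sum()
        gt, lt = self._gt, self._lt
        if self.tie_policy == "half":
            tie = 1.0 - gt - lt
            gt = gt + 0.5 * tie
            lt = lt + 0.5 * tie
        p_gt1 = gt @ w1 / n1
        p_lt1 = lt @ w1 / n1
        p_gt2 = gt @ w2 / n2
        p_lt2 = lt @ w2 / n2
        s1_fwd = p_gt1 + p_lt2 - 1.0  # a = normal isoform, b = tumor isoform
        s1_rev = p_lt1 + p_gt2 - 1.0  # a = tumor isoform
        rev = s1_rev > s1_fwd
        s1 = np.where(rev, s1_rev, s1_fwd)
        d1 = self._rd @ w1 / n1
        d2 = self._rd @ w2 / n2
        s2 = np.abs(d1 - d2)
        evaluated = (self._gt + self._lt) @ (w1 + w2)
        degenerate = evaluated == 0
        return {"s1": s1, "s2": s2, "rev": rev, "degenerate": degenerate, "m1": m1, "m2": m2}

    def best_per_gene(self, scores, require_nonneg: bool = True) -> np.ndarray:
        """Index of each gene's best eligible pair (S1 desc, S2 desc, pair order).

        Degenerate pairs are always excluded; with ``require_nonneg`` (the
        listing rule) pairs whose best-orientation S1 is negative are too.
        Genes with no eligible pair are absent from the result.
        """
        s1, s2 = scores["s1"], scores["s2"]
        ok = ~scores["degenerate"]
        if require_nonneg:
            ok &= s1 >= 0
        idx = np.flatnonzero(ok)
        if idx.size == 0:
            return idx
        order = np.lexsort((idx, -s2[idx], -s1[idx], self.pair_gene[idx]))
        idx = idx[order]
        first = np.ones(len(idx), dtype=bool)
        first[1:] = self.pair_gene[idx[1:]] != self.pair_gene[idx[:-1]]
        return idx[first]

    def ig_for_pairs(self, pair_idx: np.ndarray, scores) -> np.ndarray:
        """IG (bits) of the oriented rules at ``pair_idx`` under the labelling."""
        w1 = scores["m1"].astype(float)
        w2 = scores["m2"].astype(float)
        # vote class2 iff x_tumor >= x_normal: 1 - lt when a is tumor, 1 - gt otherwise
        rev = scores["rev"][pair_idx]
        lt = self._lt[pair_idx]
        gt = self._gt[pair_idx]
        vote_t = np.where(rev[:, None], 1.0 - lt, 1.0 - gt)
        return _ig_from_counts(vote_t @ w1, vote_t @ w2, w1.sum(), w2.sum())

    # -- ranking -----------------------------------------------------------

    def ranking(self, labels=None, sample_mask=None) -> pd.DataFrame:
        """The global one-pair-per-gene ranking as a DataFrame.

        Columns: gene, tumor_isoform, normal_isoform, s1, s2, ig, rank.
        Sorted by S1 desc, S2 desc, gene id asc.
        """
        scores = self.score_labels(labels, sample_mask)
        best = self.best_per_gene(scores)
        if best.size == 0:
            return pd.DataFrame(
                columns=["gene", "tumor_isoform", "normal_isoform", "s1", "s2", "ig", "rank"]
            )
        ig = self.ig_for_pairs(best, scores)
        genes = self.gene_names[self.pair_gene[best]]
        rev = scores["rev"][best]
        a = self._tids[self.pair_a[best]]
        b = self._tids[self.pair_b[best]]
        tumor = np.where(rev, a, b)
        normal = np.where(rev, b, a)
        df = pd.DataFrame(
            {
                "gene": genes,
                "tumor_isoform": tumor,
                "normal_isoform": normal,
                "s1": scores["s1"][best],
                "s2": scores["s2"][best],
                "ig": ig,
            }
        )
        df = df.sort_values(
            ["s1", "s2", "gene"], ascending=[False, False, True], kind="stable"
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        return df

    def max_stats(self, labels) -> tuple[float, float]:
        """(top pair's S1, max IG over per-gene best pairs) under a labelling.

        Used by the permutation null.  The S1 >= 0 listing cut is not applied
        here so the statistics stay defined even when no pair would be listed;
        fully degenerate (all-tied) data returns (nan, nan) and is reported
        explicitly by the caller.
        """
        scores = self.score_labels(labels)
        best = self.best_per_gene(scores, require_nonneg=False)
        if best.size == 0:
            return float("nan"), float("nan")
        ig = self.ig_for_pairs(best, scores)
        return float(scores["s1"][best].max()), float(ig.max())

    @property
    def all_degenerate(self) -> bool:
        """True when every same-gene pair is tied in every sample."""
        if self.n_pairs == 0:
            return True
        return bool(((self._gt + self._lt).sum(axis=1) == 0).all())


def rank_pairs(dataset: ExpressionDataset, tie_policy: str = "strict") -> pd.DataFrame:
    """Global one-pair-per-gene ranking of isoform-pair rules for a dataset."""
    return PairScorer(dataset, tie_policy=tie_policy).ranking()


def rules_from_ranking(ranking: pd.DataFrame) -> list[IsoformPairRule]:
    return [
        IsoformPairRule(
            gene=row.gene,
            tumor_isoform=row.tumor_isoform,
            normal_isoform=row.normal_isoform,
            s1=float(row.s1),
            s2=float(row.s2),
            ig=float(row.ig),
            rank=int(row.rank),
        )
        for row in ranking.itertuples(index=False)
    ]
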