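"""Rule evaluation, majority-vote classification, accuracy and blind tests.

A classifier is an odd-length ordered list of isoform-pair rules.  Each rule
votes class1 ("normal") on a sample when its tumor isoform is expressed
below its normal isoform, and class2 ("tumor") otherwise — exact expression
ties take the "else" branch and vote class2 (configurable).  The sample is
assigned the most-voted class; with k odd no vote tie is possible.

Also provides the gene-level comparison mode: gene expression is the sum of
its transcripts' TPM, and classic top-scoring-pairs ranking is run over
cross-gene pairs with each gene used in at most one listed pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .scoring import IsoformPairRule, PairScorer, rules_from_ranking

__all__ = [
    "PairClassifier",
    "ConfusionCounts",
    "evaluate_rule",
    "classify_sample",
    "accuracy",
    "blind_test",
    "gene_level_dataset",
    "rank_gene_pairs",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN counts of a two-class evaluation."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def swapped(self) -> "ConfusionCounts":
        """Counts with the positive-class designation swapped."""
        return ConfusionCounts(tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp)


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FN + FP); symmetric in the class designation."""
    if counts.total == 0:
        raise ValueError("cannot compute accuracy of zero evaluated samples")
    return (counts.tp + counts.tn) / counts.total


def evaluate_rule(
    rule: IsoformPairRule,
    expression: Mapping[str, float] | pd.Series,
    class1: str,
    class2: str,
    tie_vote: str = "class2",
) -> str:
    """Vote of a single pair rule on one sample's expression.

    class1 iff expression(tumor_isoform) < expression(normal_isoform); the
    "else" branch (including exact ties, e.g. 0 = 0) votes class2.
    """
    for iso in (rule.tumor_isoform, rule.normal_isoform):
        if iso not in expression:
            raise KeyError(f"isoform {iso!r} absent from sample expression")
    t = float(expression[rule.tumor_isoform])
    n = float(expression[rule.normal_isoform])
    if t < n:
        return class1
    if t == n and tie_vote == "class1":
        return class1
    return class2


@dataclass
class PairClassifier:
    """Ordered odd-length list of isoform-pair rules with majority voting."""

    rules: list[IsoformPairRule]
    class1: str
    class2: str
    tie_vote: str = "class2"

    def __post_init__(self) -> None:
        k = len(self.rules)
        if k < 1 or k % 2 == 0:
            raise ValueError(f"k must be odd and >= 1, got {k}")
        genes = [r.gene for r in self.rules]
        if len(set(genes)) != k:
            raise ValueError("rules must come from distinct genes")
        if self.tie_vote not in ("class1", "class2"):
            raise ValueError("tie_vote must be 'class1' or 'class2'")

    @property
    def k(self) -> int:
        return len(self.rules)

    def votes(self, expression) -> list[str]:
        return [
            evaluate_rule(r, expression, self.class1, self.class2, self.tie_vote)
            for r in self.rules
        ]

    def classify_sample(self, expression) -> tuple[str, int]:
        """(winning class, number of votes for the winner); k odd => no tie."""
        votes = self.votes(expression)
        v2 = sum(v == self.class2 for v in votes)
        v1 = self.k - v2
        return (self.class2, v2) if v2 > v1 else (self.class1, v1)

    def predict(self, expression: pd.DataFrame) -> pd.DataFrame:
        """Per-sample predictions for a transcript x sample expression matrix."""
        rows = []
        for s in expression.columns:
            cls, nv = self.classify_sample(expression[s])
            rows.append({"sample": s, "predicted": cls, "votes_for_winner": nv})
        return pd.DataFrame(rows)

    def confusion(self, expression: pd.DataFrame, true_class: Mapping[str, str]) -> ConfusionCounts:
        """Confusion counts with class2 ("tumor") as the positive class."""
        tp = tn = fp = fn = 0
        for s in expression.columns:
            pred, _ = self.classify_sample(expression[s])
            truth = true_class[s]
            if truth == self.class2:
                tp += pred == self.class2
                fn += pred != self.class2
            else:
                tn += pred == self.class1
                fp += pred != self.class1
        return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def classify_sample(model: PairClassifier, expression) -> tuple[str, int]:
    return model.classify_sample(expression)


def blind_test(
    model: PairClassifier,
    expression: pd.DataFrame,
    expected_class: str,
) -> tuple[float, pd.Series]:
    """Evaluate a trained model on held-out samples of a known class.

    Returns the fraction of samples labelled ``expected_class`` and the
    histogram (index 0..k) of the number of rules each sample fulfils for
    that class.
    """
    if expected_class not in (model.class1, model.class2):
        raise ValueError(f"unknown expected class {expected_class!r}")
    correct = 0
    hist = pd.Series(0, index=range(model.k + 1), name="n_samples")
    for s in expression.columns:
        votes = model.votes(expression[s])
        n_for = sum(v == expected_class for v in votes)
        hist[n_for] += 1
        correct += n_for > model.k / 2
    if expression.shape[1] == 0:
        raise ValueError("no samples to evaluate")
    return correct / expression.shape[1], hist


# -- gene-level comparison mode (classic kTSP over gene expression) --------


def gene_level_dataset(dataset: ExpressionDataset) -> ExpressionDataset:
    """Collapse transcripts to genes: gene TPM = sum of its isoforms' TPM.

    The resulting dataset has one feature per gene; each feature maps to
    itself so the same machinery can score cross-gene pairs.
    """
    genes = pd.Index([dataset.gene_of[t] for t in dataset.transcript_ids], name="gene")
    summed = (
        pd.DataFrame(dataset.abundance.to_numpy(), index=genes, columns=dataset.sample_ids)
        .groupby(level=0)
        .sum()
    )
    # preserve first-appearance gene order
    summed = summed.loc[pd.unique(genes)]
    return ExpressionDataset(
        summed,
        {g: g for g in summed.index},
        dict(dataset.class_of),
        class1=dataset.class1,
        class2=dataset.class2,
        pairing=dataset.pairing,
    )


def rank_gene_pairs(dataset: ExpressionDataset, tie_policy: str = "strict") -> pd.DataFrame:
    """Classic top-scoring-pairs ranking over gene-level expression.

    All cross-gene pairs are scored; pairs are listed by (S1 desc, S2 desc,
    feature ids) with each gene appearing in at most one listed pair
    (disjoint pairs).  Intended for small comparisons; the pair count grows
    quadratically in the number of genes.
    """
    gl = gene_level_dataset(dataset)
    # reuse the vectorised scorer by pretending all features share one gene
    shim = ExpressionDataset(
        gl.abundance,
        {g: "__all__" for g in gl.abundance.index},
        dict(gl.class_of),
        class1=gl.class1,
        class2=gl.class2,
    )
    scorer = PairScorer(shim, tie_policy=tie_policy)
    scores = scorer.score_labels()
    ok = ~scores["degenerate"] & (scores["s1"] >= 0)
    idx = np.flatnonzero(ok)
    a = scorer._tids[scorer.pair_a[idx]]
    b = scorer._tids[scorer.pair_b[idx]]
    rev = scores["rev"][idx]
    up = np.where(rev, a, b)  # feature higher in class2
    down = np.where(rev, b, a)
    ig = scorer.ig_for_pairs(idx, scores)
    df = pd.DataFrame(
        {
            "tumor_feature": up,
            "normal_feature": down,
            "s1": scores["s1"][idx],
            "s2": scores["s2"][idx],
            "ig": ig,
        }
    )
    df = df.sort_values(
        ["s1", "s2", "tumor_feature", "normal_feature"],
        ascending=[False, False, True, True],
        kind="stable",
    )
    used: set[str] = set()
    keep_rows = []
    for row in df.itertuples(index=False):
        if row.tumor_feature in used or row.normal_feature in used:
            continue
        used.add(row.tumor_feature)
        used.add(row.normal_feature)
        keep_rows.append(row)
    out = pd.DataFrame(keep_rows, columns=df.columns).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def classifier_from_ranking(
    ranking: pd.DataFrame,
    k: int,
    class1: str,
    class2: str,
    tie_vote: str = "class2",
) -> PairClassifier:
    """Top-k rules of a ranking as a PairClassifier (k odd, k <= len)."""
    if k > len(ranking):
        raise ValueError(f"ranking has only {len(ranking)} pairs but k={k} were requested")
    return PairClassifier(
        rules=rules_from_ranking(ranking.head(k)), class1=class1, class2=class2, tie_vote=tie_vote
    )
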