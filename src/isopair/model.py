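"""High-level modelling interface: fit once, get a results object.

Follows the Model/Results convention of statistical modelling packages:
:class:`IsoformPairModel` is built from an :class:`ExpressionDataset` (or
from files), and :meth:`~IsoformPairModel.fit` runs the full workflow —
pair ranking, leave-one-pair-out cross-validation and k_opt selection,
max-statistic permutation significance, and switch detection — returning an
:class:`IsoformPairResults` that carries the estimates and diagnostics and
renders a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import PairClassifier, blind_test
from .datasets import ExpressionDataset, filter_genes
from .model_selection import CrossValResult, build_final_model, cross_validate
from .scoring import PairScorer
from .significance import PermutationNull, permutation_test, significant_pairs
from .switches import detect_switches, switch_occurrence_matrix

__all__ = ["IsoformPairModel", "IsoformPairResults"]


class IsoformPairModel:
    """Rank-reversal isoform-pair model of a two-class expression dataset.

    Parameters
    ----------
    dataset : ExpressionDataset
        TPM matrix with gene map, two-class labels and (for cross-validation)
        patient pairing.
    tie_policy : "strict" (default) or "half"
        How exact expression ties enter the S1 frequencies.
    gene_filter : bool
        Drop single-isoform / symbol-less genes before fitting (default True).
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        tie_policy: str = "strict",
        gene_filter: bool = True,
    ) -> None:
        import warnings

        if gene_filter:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dataset = filter_genes(dataset)
        self.dataset = dataset
        self.tie_policy = tie_policy

    @classmethod
    def from_files(
        cls,
        expression: str,
        labels: str,
        *,
        units: str = "tpm",
        lengths: str | None = None,
        **kwargs,
    ) -> "IsoformPairModel":
        from .io import read_dataset

        return cls(read_dataset(expression, labels, units=units, lengths=lengths), **kwargs)

    def fit(
        self,
        k_max: int = 11,
        n_perm: int = 1000,
        seed: int | None = None,
        min_s1: float = 0.5,
        max_rho: float = -0.8,
        min_tpm: float = 1.0,
        cross_validation: bool = True,
    ) -> "IsoformPairResults":
        """Run ranking, CV, permutation significance and switch detection."""
        scorer = PairScorer(self.dataset, tie_policy=self.tie_policy)
        ranking = scorer.ranking()
        cv = None
        classifier = None
        if cross_validation and self.dataset.pairing:
            cv = cross_validate(self.dataset, k_max=k_max, tie_policy=self.tie_policy)
            if len(ranking) >= cv.k_opt:
                classifier = build_final_model(self.dataset, cv.k_opt, ranking=ranking)
        null = permutation_test(self.dataset, n_perm=n_perm, seed=seed, scorer=scorer)
        sig = significant_pairs(ranking, null)
        switches = detect_switches(
            sig, self.dataset, min_s1=min_s1, max_rho=max_rho, min_tpm=min_tpm
        )
        return IsoformPairResults(
            model=self,
            ranking=ranking,
            cv=cv,
            classifier=classifier,
            null=null,
            significant=sig,
            switches=switches,
            seed=seed,
        )


@dataclass
class IsoformPairResults:
    """Fitted ranking, cross-validation, significance and switches."""

    model: IsoformPairModel
    ranking: pd.DataFrame
    cv: CrossValResult | None
    classifier: PairClassifier | None
    null: PermutationNull
    significant: pd.DataFrame
    switches: pd.DataFrame
    seed: int | None = None

    @property
    def k_opt(self) -> int | None:
        return self.cv.k_opt if self.cv else None

    def predict(self, expression: pd.DataFrame) -> pd.DataFrame:
        """Per-sample class predictions of the minimal classifier."""
        if self.classifier is None:
            raise ValueError("no classifier fitted (cross-validation was not run)")
        return self.classifier.predict(expression)

    def blind_test(self, expression: pd.DataFrame, expected_class: str):
        """Fraction correct + vote histogram on held-out samples."""
        if self.classifier is None:
            raise ValueError("no classifier fitted (cross-validation was not run)")
        return blind_test(self.classifier, expression, expected_class)

    def occurrence_matrix(self, samples=None) -> pd.DataFrame:
        return switch_occurrence_matrix(self.switches, self.model.dataset, samples)

    def summary(self) -> str:
        ds = self.model.dataset
        lines = [
            "Isoform-pair reversal model",
            "=" * 60,
            f"transcripts: {len(ds.transcript_ids)}   genes: {len(ds.genes)}   "
            f"samples: {ds.n_samples} ({ds.class1} vs {ds.class2})",
            f"tie policy: {self.model.tie_policy}   seed: {self.seed}",
            "",
            f"listed pairs:        {len(self.ranking)}",
            f"permutations:        {self.null.n_perm}"
            + ("  [degenerate: all pairs tied]" if self.null.all_degenerate else ""),
        ]
        if not self.null.all_degenerate:
            lines += [
                f"S1 threshold (max):  {self.null.threshold_s1:.4f}",
                f"IG threshold (max):  {self.null.threshold_ig:.4f}",
            ]
        lines += [
            f"significant pairs:   {len(self.significant)}",
            f"isoform switches:    {len(self.switches)}",
        ]
        if self.cv is not None:
            acc = ", ".join(f"k={k}: {a:.3f}" for k, a in self.cv.mean_accuracy.items())
            lines += ["", f"cross-validation mean accuracy  {acc}", f"k_opt: {self.cv.k_opt}"]
        if len(self.ranking):
            lines += ["", "top pairs (gene, tumor_isoform, normal_isoform, S1, S2, IG):"]
            for row in self.ranking.head(5).itertuples(index=False):
                lines.append(
                    f"  {row.rank:>3} {row.gene} {row.tumor_isoform} {row.normal_isoform} "
                    f"{row.s1:.4f} {row.s2:.3f} {row.ig:.4f}"
                )
        return "\n".join(lines)

    def plot_cv_accuracy(self, ax=None):
        """Mean cross-validation accuracy vs model size k."""
        if self.cv is None:
            raise ValueError("cross-validation was not run")
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ks = list(self.cv.mean_accuracy)
        ax.plot(ks, [self.cv.mean_accuracy[k] for k in ks], "o-")
        ax.axvline(self.cv.k_opt, ls="--", color="grey")
        ax.set_xlabel("number of isoform-pair rules k")
        ax.set_ylabel("mean CV accuracy")
        ax.set_ylim(0, 1.05)
        return ax

    def plot_null(self, ax=None):
        """Histogram of the permutation max-S1 null with the S1 threshold."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.null.max_s1[~np.isnan(self.null.max_s1)], bins=30, color="steelblue")
        if not self.null.all_degenerate:
            ax.axvline(self.null.threshold_s1, color="red", ls="--", label="threshold")
            ax.legend()
        ax.set_xlabel("per-permutation max S1")
        ax.set_ylabel("permutations")
        return ax
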