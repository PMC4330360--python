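"""Leave-one-patient-pair-out cross-validation and minimal model size.

Each fold holds out one patient's tumor+normal sample pair, recomputes the
full pair ranking on the remaining samples, and evaluates the top-k
classifiers (k = 1, 3, 5, ..., k_max) on the two held-out samples.  The
optimal model size k_opt is the smallest odd k achieving the highest mean
accuracy over folds (equality judged after rounding to 1e-10 to avoid float
artifacts), and the final model takes the top k_opt pairs of the global
ranking computed on all training samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import PairClassifier, classifier_from_ranking
from .datasets import ExpressionDataset
from .scoring import PairScorer

__all__ = ["CrossValResult", "cross_validate", "select_k_opt", "build_final_model"]

_K_ROUND = 10  # decimals for k_opt accuracy ties


@dataclass
class CrossValResult:
    """Per-k mean accuracies, per-fold detail and the selected k_opt."""

    mean_accuracy: dict[int, float]
    fold_accuracy: pd.DataFrame  # folds x k
    fold_rankings: list[pd.DataFrame] = field(repr=False, default_factory=list)
    k_opt: int = 1

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": list(self.mean_accuracy), "mean_accuracy": list(self.mean_accuracy.values())}
        )


def select_k_opt(mean_accuracy: dict[int, float]) -> int:
    """Smallest odd k among those attaining the maximal mean accuracy."""
    if not mean_accuracy:
        raise ValueError("empty accuracy table")
    rounded = {k: round(a, _K_ROUND) for k, a in mean_accuracy.items()}
    best = max(rounded.values())
    return min(k for k, a in rounded.items() if a == best)


def cross_validate(
    dataset: ExpressionDataset,
    k_max: int = 11,
    tie_policy: str = "strict",
    keep_fold_rankings: bool = False,
) -> CrossValResult:
    """Leave-one-patient-pair-out CV over the paired samples.

    Requires dataset.pairing with at least 3 patient pairs.  Folds are taken
    in pairing order and are fully deterministic.  A fold whose ranking lists
    fewer than k pairs is evaluated with the largest available odd k.
    """
    if not dataset.pairing:
        raise ValueError(
            "cross-validation needs patient pairing; supply a label file with "
            "a 'patient' column or a pairing map"
        )
    if len(dataset.pairing) < 3:
        raise ValueError("need at least 3 patient pairs for cross-validation")
    if k_max < 1 or k_max % 2 == 0:
        raise ValueError("k_max must be odd and >= 1")

    scorer = PairScorer(dataset, tie_policy=tie_policy)
    sample_pos = {s: i for i, s in enumerate(dataset.sample_ids)}
    ks = list(range(1, k_max + 1, 2))
    fold_rows = []
    fold_rankings = []
    for patient, (s_normal, s_tumor) in dataset.pairing.items():
        mask = np.ones(dataset.n_samples, dtype=bool)
        mask[[sample_pos[s_normal], sample_pos[s_tumor]]] = False
        ranking = scorer.ranking(sample_mask=mask)
        if keep_fold_rankings:
            fold_rankings.append(ranking)
        held = dataset.abundance[[s_normal, s_tumor]]
        truth = {s_normal: dataset.class1, s_tumor: dataset.class2}
        row = {"patient": patient}
        for k in ks:
            k_eff = min(k, len(ranking))
            if k_eff % 2 == 0:
                k_eff -= 1
            if k_eff < 1:
                row[k] = np.nan
                continue
            model = classifier_from_ranking(
                ranking, k_eff, dataset.class1, dataset.class2
            )
            counts = model.confusion(held, truth)
            row[k] = (counts.tp + counts.tn) / counts.total
        fold_rows.append(row)

    fold_df = pd.DataFrame(fold_rows).set_index("patient")
    mean_acc = {k: float(fold_df[k].mean()) for k in ks}
    return CrossValResult(
        mean_accuracy=mean_acc,
        fold_accuracy=fold_df,
        fold_rankings=fold_rankings,
        k_opt=select_k_opt(mean_acc),
    )


def build_final_model(
    dataset: ExpressionDataset,
    k_opt: int,
    tie_policy: str = "strict",
    ranking: pd.DataFrame | None = None,
) -> PairClassifier:
    """Top k_opt pairs of the global (all-training-data) ranking as the model."""
    if ranking is None:
        from .scoring import rank_pairs

        ranking = rank_pairs(dataset, tie_policy=tie_policy)
    if len(ranking) < k_opt:
        raise ValueError(
            f"global ranking lists {len(ranking)} pairs, fewer than k_opt={k_opt}"
        )
    return classifier_from_ranking(ranking, k_opt, dataset.class1, dataset.class2)
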