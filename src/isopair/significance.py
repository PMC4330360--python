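"""Label-permutation null for pair scores and the subtype recurrence procedure.

Significance of the listed isoform pairs is assessed against a max-statistic
permutation null: the class labels are shuffled n_perm times (class sizes
preserved), the pair ranking is recomputed for each shuffle, and the top
pair's S1 and the maximum IG are recorded.  A pair is significant when its
S1 AND its IG strictly exceed the respective maxima over all permutations —
a family-wise-error-controlling threshold.  Empirical p-values
(1 + #{perm >= observed}) / (n_perm + 1) are reported alongside.

The subtype mode repeatedly subsamples a balanced target-vs-pool two-class
set, reruns ranking + permutation test on each subsample, and reports per
pair the fraction of iterations in which it was significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .model_selection import cross_validate
from .scoring import PairScorer

__all__ = [
    "PermutationNull",
    "SubtypeRecurrence",
    "permutation_test",
    "significant_pairs",
    "subtype_recurrence",
]


@dataclass
class PermutationNull:
    """Null distributions of the per-permutation max S1 and max IG."""

    n_perm: int
    max_s1: np.ndarray
    max_ig: np.ndarray
    seed: int | None
    all_degenerate: bool = False

    @property
    def threshold_s1(self) -> float:
        return float(np.max(self.max_s1))

    @property
    def threshold_ig(self) -> float:
        return float(np.max(self.max_ig))

    def pvalue_s1(self, s1: float) -> float:
        return float((1 + np.sum(self.max_s1 >= s1)) / (self.n_perm + 1))

    def pvalue_ig(self, ig: float) -> float:
        return float((1 + np.sum(self.max_ig >= ig)) / (self.n_perm + 1))


def _permuted_labels(rng: np.random.Generator, labels: np.ndarray) -> np.ndarray:
    return labels[rng.permutation(len(labels))]


def permutation_test(
    dataset: ExpressionDataset,
    n_perm: int = 1000,
    seed: int | None = None,
    tie_policy: str = "strict",
    scorer: PairScorer | None = None,
    permute_with_cv: bool = False,
) -> PermutationNull:
    """Max-statistic null from n_perm label permutations.

    Permutations preserve class sizes and ignore patient pairing.  A single
    seeded generator draws permutation i's labels sequentially, so runs are
    reproducible and prefix-stable in n_perm.  ``permute_with_cv`` runs the
    full cross-validation at each permutation (the literal, much slower
    variant); the recorded statistics are identical since only the ranking
    feeds the thresholds.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    for label in (dataset.class1, dataset.class2):
        if len(dataset.samples_of_class(label)) < 2:
            raise ValueError(f"class {label!r} needs at least 2 samples")
    scorer = scorer or PairScorer(dataset, tie_policy=tie_policy)
    if scorer.all_degenerate:
        return PermutationNull(
            n_perm=n_perm,
            max_s1=np.full(n_perm, np.nan),
            max_ig=np.full(n_perm, np.nan),
            seed=seed,
            all_degenerate=True,
        )
    rng = np.random.default_rng(seed)
    labels = scorer.labels
    max_s1 = np.empty(n_perm)
    max_ig = np.empty(n_perm)
    for i in range(n_perm):
        perm = _permuted_labels(rng, labels)
        if permute_with_cv:
            # Literal variant: rerun the CV under the permuted labels, pairing
            # permuted class1/class2 samples in order.  Only the ranking feeds
            # the recorded statistics, so the thresholds are unchanged.
            sids = np.asarray(dataset.sample_ids, dtype=object)
            c1 = list(sids[perm == dataset.class1])
            c2 = list(sids[perm == dataset.class2])
            perm_ds = dataset.subset_samples(
                dataset.sample_ids, class_of=dict(zip(dataset.sample_ids, perm))
            )
            perm_ds.class1, perm_ds.class2 = dataset.class1, dataset.class2
            perm_ds.pairing = {f"perm{j}": (a, b) for j, (a, b) in enumerate(zip(c1, c2))}
            if len(perm_ds.pairing) >= 3:
                cross_validate(perm_ds, k_max=1, tie_policy=tie_policy)
        max_s1[i], max_ig[i] = scorer.max_stats(perm)
    return PermutationNull(n_perm=n_perm, max_s1=max_s1, max_ig=max_ig, seed=seed)


def significant_pairs(ranking: pd.DataFrame, null: PermutationNull) -> pd.DataFrame:
    """Pairs whose S1 AND IG strictly exceed the permutation maxima.

    Adds empirical p-value columns; a degenerate (all-tied) null yields no
    significant pairs.
    """
    out = ranking.copy()
    if null.all_degenerate or len(out) == 0:
        out["p_s1"] = np.nan
        out["p_ig"] = np.nan
        return out.iloc[0:0]
    out["p_s1"] = [null.pvalue_s1(v) for v in out["s1"]]
    out["p_ig"] = [null.pvalue_ig(v) for v in out["ig"]]
    keep = (out["s1"] > null.threshold_s1) & (out["ig"] > null.threshold_ig)
    return out[keep].reset_index(drop=True)


@dataclass
class SubtypeRecurrence:
    """Per-pair significance frequencies over balanced subsampling iterations."""

    frequencies: pd.DataFrame  # gene, tumor_isoform, normal_isoform, n_significant, frequency
    n_iter: int
    group_size: int
    pool_per_other: int
    model_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)


def subtype_recurrence(
    dataset: ExpressionDataset,
    subtype_of,
    target: str,
    n_iter: int = 100,
    group_size: int = 45,
    pool_per_other: int = 15,
    n_perm: int = 1000,
    seed: int | None = None,
    freq_cutoff: float = 0.8,
    tie_policy: str = "strict",
) -> SubtypeRecurrence:
    """One-vs-pool subtype analysis with per-iteration permutation tests.

    At each iteration, ``group_size`` samples of the target subtype and
    ``pool_per_other`` samples from each other subtype are drawn without
    replacement; the pooled samples form class1 and the target class2.  The
    pair ranking and a permutation test are run on the subsample and the
    significant pairs recorded.  Pairs significant in more than
    ``freq_cutoff`` of iterations form the subtype model (count truncated
    to odd).
    """
    subtype_of = pd.Series(subtype_of)
    subtypes = sorted(set(subtype_of))
    if target not in subtypes:
        raise ValueError(f"target subtype {target!r} not among {subtypes}")
    target_samples = [s for s in subtype_of.index if subtype_of[s] == target]
    others = {
        st: [s for s in subtype_of.index if subtype_of[s] == st]
        for st in subtypes
        if st != target
    }
    if len(target_samples) < group_size:
        raise ValueError(
            f"target subtype has {len(target_samples)} samples < group_size={group_size}"
        )
    for st, ss in others.items():
        if len(ss) < pool_per_other:
            raise ValueError(f"subtype {st!r} has {len(ss)} samples < pool_per_other={pool_per_other}")

    rng = np.random.default_rng(seed)
    counts: dict[tuple[str, str, str], int] = {}
    s1_sums: dict[tuple[str, str, str], float] = {}
    for _ in range(n_iter):
        chosen_target = list(rng.choice(target_samples, size=group_size, replace=False))
        chosen_pool: list[str] = []
        for st in sorted(others):
            chosen_pool += list(rng.choice(others[st], size=pool_per_other, replace=False))
        samples = chosen_pool + chosen_target
        class_of = {s: ("pool" if s in set(chosen_pool) else target) for s in samples}
        sub = dataset.subset_samples(samples, class_of=class_of)
        # pool sorts before most labels; force designation: pool = class1
        sub.class1, sub.class2 = "pool", target
        scorer = PairScorer(sub, tie_policy=tie_policy)
        ranking = scorer.ranking()
        null = permutation_test(
            sub, n_perm=n_perm, seed=int(rng.integers(2**31 - 1)), scorer=scorer
        )
        sig = significant_pairs(ranking, null)
        for row in sig.itertuples(index=False):
            key = (row.gene, row.tumor_isoform, row.normal_isoform)
            counts[key] = counts.get(key, 0) + 1
            s1_sums[key] = s1_sums.get(key, 0.0) + row.s1

    rows = [
        {
            "gene": g,
            "tumor_isoform": t,
            "normal_isoform": n,
            "n_significant": c,
            "frequency": c / n_iter,
            "mean_s1": s1_sums[(g, t, n)] / c,
        }
        for (g, t, n), c in counts.items()
    ]
    freq = pd.DataFrame(
        rows,
        columns=["gene", "tumor_isoform", "normal_isoform", "n_significant", "frequency", "mean_s1"],
    ).sort_values(
        ["frequency", "mean_s1", "gene"], ascending=[False, False, True], kind="stable"
    ).reset_index(drop=True)

    model = freq[freq["frequency"] > freq_cutoff]
    if len(model) % 2 == 0 and len(model) > 0:
        model = model.iloc[:-1]
    return SubtypeRecurrence(
        frequencies=freq,
        n_iter=n_iter,
        group_size=group_size,
        pool_per_other=pool_per_other,
        model_pairs=model.reset_index(drop=True),
    )
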