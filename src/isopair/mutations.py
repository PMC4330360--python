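"""Statistics linking isoform switches to somatic mutations.

For each switch, let S be the set of tumor samples carrying the switch
(tumor rule fulfilled) and M the set of samples with at least one mutation
overlapping the switch region, both restricted to the universe of samples
with both expression and mutation data.  The module computes:

* Jaccard co-occurrence J = |M∩S| / |M∪S|;
* plug-in mutual information (bits) of the two binary indicators;
* mutual-exclusion score mx = 2·min(n10, n01)/N, where n10 counts samples
  with the switch but no mutation and n01 the converse;
* z-scores for each statistic against a background of the 100 genes nearest
  in median isoform length (same S, that gene's mutated samples);
* a two-sided Mann–Whitney test comparing the per-sample ΔPSI
  (PSI(tumor isoform) − PSI(normal isoform)) between mutated and
  non-mutated tumor samples, Benjamini–Hochberg-corrected across switches.

Mutation/region overlap uses closed 1-based intervals; ``scope`` selects
the union of the two switch transcripts' spans or the whole gene span.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .datasets import (
    ExpressionDataset,
    MutationTable,
    PROTEIN_AFFECTING_CLASSES,
    TranscriptStructure,
)

__all__ = [
    "MutationAssociation",
    "mutated_samples",
    "jaccard_association",
    "mutual_information_association",
    "mutual_exclusion",
    "background_zscore",
    "delta_psi_mutation_test",
    "associate_switches",
]


@dataclass
class MutationAssociation:
    """All per-switch mutation-association statistics."""

    switch_id: str
    gene: str
    n_universe: int
    n_switch: int
    n_mutated: int
    jaccard: float
    j_zscore: float | None
    mutual_information: float
    mi_zscore: float | None
    mx: float
    mx_zscore: float | None
    delta_psi_pvalue: float | None
    bh_adjusted_pvalue: float | None = None


def _span_union(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    spans = sorted(spans)
    merged = [spans[0]]
    for a, b in spans[1:]:
        if a <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def _gene_regions(
    transcripts: list[str],
    structures: dict[str, TranscriptStructure],
    scope: str,
) -> tuple[str, list[tuple[int, int]]]:
    missing = [t for t in transcripts if t not in structures]
    if missing:
        raise KeyError(f"no genomic structure for transcript(s) {missing}")
    chroms = {structures[t].chrom for t in transcripts}
    if len(chroms) != 1:
        raise ValueError(f"transcripts {transcripts} on different chromosomes")
    spans = [structures[t].span for t in transcripts]
    if scope == "gene":
        lo = min(a for a, _ in spans)
        hi = max(b for _, b in spans)
        regions = [(lo, hi)]
    elif scope == "transcript":
        regions = _span_union(spans)
    else:
        raise ValueError("scope must be 'transcript' or 'gene'")
    return chroms.pop(), regions


def mutated_samples(
    transcripts: list[str],
    mutations: MutationTable,
    structures: dict[str, TranscriptStructure],
    scope: str = "transcript",
    protein_affecting_only: bool = False,
) -> set[str]:
    """Samples with >= 1 mutation intersecting the region of ``transcripts``.

    ``scope="transcript"`` uses the union of the transcripts' spans;
    ``scope="gene"`` the single interval covering all of them (so intronic
    mutations between the transcripts count).  Intersection is closed-interval.
    """
    chrom, regions = _gene_regions(transcripts, structures, scope)
    df = mutations.records
    df = df[df["chrom"].astype(str) == chrom]
    if protein_affecting_only:
        df = df[df["mut_class"].isin(PROTEIN_AFFECTING_CLASSES)]
    hit = np.zeros(len(df), dtype=bool)
    start = df["start"].to_numpy()
    end = df["end"].to_numpy()
    for a, b in regions:
        hit |= (start <= b) & (end >= a)
    return set(df.loc[hit, "sample"])


def jaccard_association(S: set, M: set) -> float:
    """J = |M ∩ S| / |M ∪ S|; 0 (flagged by the caller) when both are empty."""
    union = M | S
    if not union:
        return 0.0
    return len(M & S) / len(union)


def _h(p: float) -> float:
    return 0.0 if p in (0.0, 1.0) else -p * math.log2(p) - (1 - p) * math.log2(1 - p)


def mutual_information_association(S: set, M: set, N: int) -> float:
    """Plug-in MI (bits) of the switch and mutation indicators over N samples."""
    if N < 1:
        raise ValueError("N must be >= 1")
    n11 = len(S & M)
    n10 = len(S - M)
    n01 = len(M - S)
    n00 = N - n11 - n10 - n01
    if n00 < 0:
        raise ValueError("S and M must be subsets of the N-sample universe")
    mi = 0.0
    ps = len(S) / N
    pm = len(M) / N
    for nij, psi_, pmj in (
        (n11, ps, pm),
        (n10, ps, 1 - pm),
        (n01, 1 - ps, pm),
        (n00, 1 - ps, 1 - pm),
    ):
        p = nij / N
        if p > 0:
            mi += p * math.log2(p / (psi_ * pmj))
    return max(mi, 0.0)


def mutual_exclusion(n10: int, n01: int, N: int) -> float:
    """mx = 2·min(n10, n01)/N  (in [0, 1])."""
    if n10 < 0 or n01 < 0 or n10 + n01 > N:
        raise ValueError("need 0 <= n10, n01 and n10 + n01 <= N")
    return 2.0 * min(n10, n01) / N


def background_zscore(
    observed: float,
    background_values,
) -> float | None:
    """z = (obs − mean)/sd over background statistic values; None if sd = 0."""
    vals = np.asarray(list(background_values), dtype=float)
    sd = vals.std(ddof=0)
    if vals.max() == vals.min() or not np.isfinite(sd):
        warnings.warn("constant background; z-score undefined", stacklevel=2)
        return None
    return float((observed - vals.mean()) / sd)


def _median_isoform_length(
    gene: str,
    transcripts_of: dict[str, list[str]],
    structures: dict[str, TranscriptStructure],
) -> float:
    lens = [structures[t].length for t in transcripts_of[gene] if t in structures]
    return float(np.median(lens)) if lens else np.nan


def select_background_genes(
    gene: str,
    transcripts_of: dict[str, list[str]],
    structures: dict[str, TranscriptStructure],
    n_background: int = 100,
) -> list[str]:
    """The n genes (≥2 isoforms, with structures) nearest in median isoform length.

    Distance is |median transcript length difference|; ties break by gene id.
    """
    target = _median_isoform_length(gene, transcripts_of, structures)
    cands = []
    for g, ts in transcripts_of.items():
        if g == gene or len(ts) < 2:
            continue
        m = _median_isoform_length(g, transcripts_of, structures)
        if np.isnan(m):
            continue
        cands.append((abs(m - target), g))
    cands.sort()
    if len(cands) < n_background:
        raise ValueError(
            f"only {len(cands)} candidate background genes available, need {n_background}"
        )
    return [g for _, g in cands[:n_background]]


def delta_psi_mutation_test(
    tumor_iso: str,
    normal_iso: str,
    dataset: ExpressionDataset,
    mutated: set[str],
    universe: list[str],
    paired: bool = False,
) -> float | None:
    """Two-sided Mann–Whitney p for ΔPSI in mutated vs non-mutated tumor samples.

    ΔPSI is PSI(tumor isoform) − PSI(normal isoform) per tumor sample (the
    default), or the per-patient tumor-minus-normal difference of that
    quantity when ``paired`` is set.  Returns None (flagged) when either
    group has no sample with defined ΔPSI.
    """
    psi = dataset.psi
    tumor_samples = [
        s for s in universe if dataset.class_of.get(s) == dataset.class2
    ]
    if paired:
        if not dataset.pairing:
            raise ValueError("paired ΔPSI requires patient pairing")
        deltas = {}
        for s_n, s_t in dataset.pairing.values():
            if s_t not in tumor_samples:
                continue
            d_t = psi.loc[tumor_iso, s_t] - psi.loc[normal_iso, s_t]
            d_n = psi.loc[tumor_iso, s_n] - psi.loc[normal_iso, s_n]
            deltas[s_t] = d_t - d_n
    else:
        deltas = {
            s: psi.loc[tumor_iso, s] - psi.loc[normal_iso, s] for s in tumor_samples
        }
    grp_mut = [d for s, d in deltas.items() if s in mutated and not np.isnan(d)]
    grp_non = [d for s, d in deltas.items() if s not in mutated and not np.isnan(d)]
    if not grp_mut or not grp_non:
        warnings.warn("empty ΔPSI group; Mann–Whitney p undefined", stacklevel=2)
        return None
    if len(set(grp_mut) | set(grp_non)) == 1:
        return 1.0  # all values tied
    res = mannwhitneyu(grp_mut, grp_non, alternative="two-sided", method="auto")
    return float(res.pvalue)


def associate_switches(
    switches: pd.DataFrame,
    occurrence: pd.DataFrame,
    dataset: ExpressionDataset,
    mutations: MutationTable,
    structures: dict[str, TranscriptStructure],
    scope: str = "transcript",
    protein_affecting_only: bool = False,
    n_background: int = 100,
    alpha: float = 0.05,
    profiled_samples: set[str] | None = None,
) -> pd.DataFrame:
    """All mutation-association statistics per switch, BH-corrected ΔPSI p.

    The sample universe is the tumor samples with both expression and
    mutation data.  Background z-scores compare each statistic to its value
    over the ``n_background`` genes nearest in median isoform length, using
    the same switch-sample set S and each background gene's own mutated set.
    """
    tumor_samples = [s for s in dataset.sample_ids if dataset.class_of[s] == dataset.class2]
    # universe = tumor samples with both expression and DNA data; without an
    # explicit profiled set, every tumor sample is assumed DNA-profiled
    if profiled_samples is not None:
        universe = [s for s in tumor_samples if s in profiled_samples]
    else:
        universe = tumor_samples
    N = len(universe)
    if N == 0:
        raise ValueError("no tumor samples in the mutation universe")
    transcripts_of = dataset.transcripts_of_gene()
    rows = []
    pvals: list[float | None] = []
    for sid, row in zip(occurrence.index, switches.itertuples(index=False)):
        S = {s for s in universe if occurrence.loc[sid, s] == 1}
        pair = [row.tumor_isoform, row.normal_isoform]
        M = mutated_samples(pair, mutations, structures, scope, protein_affecting_only) & set(
            universe
        )
        j = jaccard_association(S, M)
        mi = mutual_information_association(S, M, N)
        n10 = len(S - M)
        n01 = len(M - S)
        mx = mutual_exclusion(n10, n01, N)

        bg = select_background_genes(row.gene, transcripts_of, structures, n_background)
        bg_j, bg_mi, bg_mx = [], [], []
        for g in bg:
            Mg = mutated_samples(
                transcripts_of[g], mutations, structures, scope, protein_affecting_only
            ) & set(universe)
            bg_j.append(jaccard_association(S, Mg))
            bg_mi.append(mutual_information_association(S, Mg, N))
            bg_mx.append(mutual_exclusion(len(S - Mg), len(Mg - S), N))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            jz = background_zscore(j, bg_j)
            miz = background_zscore(mi, bg_mi)
            mxz = background_zscore(mx, bg_mx)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = delta_psi_mutation_test(
                row.tumor_isoform, row.normal_isoform, dataset, M, universe
            )
        pvals.append(p)
        rows.append(
            MutationAssociation(
                switch_id=sid,
                gene=row.gene,
                n_universe=N,
                n_switch=len(S),
                n_mutated=len(M),
                jaccard=j,
                j_zscore=jz,
                mutual_information=mi,
                mi_zscore=miz,
                mx=mx,
                mx_zscore=mxz,
                delta_psi_pvalue=p,
            )
        )

    tested = [i for i, p in enumerate(pvals) if p is not None]
    if tested:
        _, adj, _, _ = multipletests([pvals[i] for i in tested], alpha=alpha, method="fdr_bh")
        for i, a in zip(tested, adj):
            rows[i].bh_adjusted_pvalue = float(a)
    return pd.DataFrame([r.__dict__ for r in rows])
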