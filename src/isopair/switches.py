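"""Isoform switches: significant pairs where the dominant isoform changes.

A significant isoform pair is called a *switch* when
  (1) S1 > 0.5 — the relative order changes in more than 75% of samples,
  (2) the two isoforms' PSI values anti-correlate across the paired samples
      (Spearman rho < -0.8, samples with missing PSI dropped pairwise), and
  (3) each isoform averages > 1 TPM in at least one of the two classes.

The PSI correlation is computed jointly over the paired tumor and normal
samples: a genuine reversal puts the two classes at opposite ends of both
isoforms' PSI ranges, which is what drives rho strongly negative.  For a
two-isoform gene the PSIs are exactly complementary where defined, so rho
is -1 whenever both vary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .datasets import ExpressionDataset, TranscriptStructure

__all__ = [
    "SwitchRecord",
    "detect_switches",
    "classify_protein_impact",
    "switch_occurrence_matrix",
    "PROTEIN_IMPACT_CATEGORIES",
]

PROTEIN_IMPACT_CATEGORIES = (
    "no CDS",
    "no normal CDS",
    "no tumor CDS",
    "no protein affected",
    "protein affected",
)


@dataclass(frozen=True)
class SwitchRecord:
    """A significant isoform pair passing all three switch filters."""

    gene: str
    tumor_isoform: str
    normal_isoform: str
    s1: float
    ig: float
    spearman_rho: float
    mean_tpm_tumor_iso_in_tumor: float
    mean_tpm_tumor_iso_in_normal: float
    mean_tpm_normal_iso_in_tumor: float
    mean_tpm_normal_iso_in_normal: float
    protein_impact: str | None = None

    def __post_init__(self) -> None:
        if not self.s1 > 0.5:
            raise ValueError(f"{self.gene}: switch requires s1 > 0.5, got {self.s1}")
        if not self.spearman_rho < -0.8:
            raise ValueError(f"{self.gene}: switch requires rho < -0.8, got {self.spearman_rho}")
        t_ok = max(self.mean_tpm_tumor_iso_in_tumor, self.mean_tpm_tumor_iso_in_normal) > 1
        n_ok = max(self.mean_tpm_normal_iso_in_tumor, self.mean_tpm_normal_iso_in_normal) > 1
        if not (t_ok and n_ok):
            raise ValueError(f"{self.gene}: both isoforms must average > 1 TPM in some class")


def _paired_sample_ids(dataset: ExpressionDataset) -> list[str]:
    if dataset.pairing:
        out: list[str] = []
        for s1, s2 in dataset.pairing.values():
            out += [s1, s2]
        return out
    return dataset.sample_ids


def detect_switches(
    significant: pd.DataFrame,
    dataset: ExpressionDataset,
    min_s1: float = 0.5,
    max_rho: float = -0.8,
    min_tpm: float = 1.0,
    min_obs: int = 3,
) -> pd.DataFrame:
    """Filter significant pairs down to isoform switches.

    Returns a DataFrame with the SwitchRecord fields; pairs with fewer than
    ``min_obs`` complete PSI observations are dropped with a warning.
    """
    psi = dataset.psi
    tpm = dataset.abundance
    samples = _paired_sample_ids(dataset)
    c1_samples = [s for s in dataset.sample_ids if dataset.class_of[s] == dataset.class1]
    c2_samples = [s for s in dataset.sample_ids if dataset.class_of[s] == dataset.class2]
    rows = []
    for row in significant.itertuples(index=False):
        if not row.s1 > min_s1:
            continue
        t, n = row.tumor_isoform, row.normal_isoform
        mean_t_c2 = float(tpm.loc[t, c2_samples].mean())
        mean_t_c1 = float(tpm.loc[t, c1_samples].mean())
        mean_n_c2 = float(tpm.loc[n, c2_samples].mean())
        mean_n_c1 = float(tpm.loc[n, c1_samples].mean())
        if not (max(mean_t_c1, mean_t_c2) > min_tpm and max(mean_n_c1, mean_n_c2) > min_tpm):
            continue
        pt = psi.loc[t, samples].to_numpy(dtype=float)
        pn = psi.loc[n, samples].to_numpy(dtype=float)
        ok = ~np.isnan(pt) & ~np.isnan(pn)
        if ok.sum() < min_obs:
            warnings.warn(
                f"{row.gene}: only {int(ok.sum())} complete PSI observations; pair dropped",
                stacklevel=2,
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant input -> nan rho, filtered below
            rho = spearmanr(pt[ok], pn[ok]).statistic
        if not (np.isfinite(rho) and rho < max_rho):
            continue
        rows.append(
            {
                "gene": row.gene,
                "tumor_isoform": t,
                "normal_isoform": n,
                "s1": float(row.s1),
                "ig": float(row.ig),
                "spearman_rho": float(rho),
                "mean_tpm_tumor_iso_in_tumor": mean_t_c2,
                "mean_tpm_tumor_iso_in_normal": mean_t_c1,
                "mean_tpm_normal_iso_in_tumor": mean_n_c2,
                "mean_tpm_normal_iso_in_normal": mean_n_c1,
            }
        )
    cols = [
        "gene",
        "tumor_isoform",
        "normal_isoform",
        "s1",
        "ig",
        "spearman_rho",
        "mean_tpm_tumor_iso_in_tumor",
        "mean_tpm_tumor_iso_in_normal",
        "mean_tpm_normal_iso_in_tumor",
        "mean_tpm_normal_iso_in_normal",
    ]
    out = pd.DataFrame(rows, columns=cols)
    # construct records to assert every emitted row passes the filters
    for r in out.itertuples(index=False):
        SwitchRecord(**r._asdict())
    return out


def classify_protein_impact(
    switch,
    cds_of: dict[str, str | None],
) -> str:
    """Map a switch to one of the five protein-impact categories.

    ``cds_of`` maps transcript id -> CDS (amino-acid or nucleotide) sequence,
    or None for a non-coding transcript.  A transcript absent from the
    annotation yields "unknown" (excluded from summaries).
    """
    t, n = switch.tumor_isoform, switch.normal_isoform
    if t not in cds_of or n not in cds_of:
        return "unknown"
    cds_t, cds_n = cds_of[t], cds_of[n]
    if cds_t is None and cds_n is None:
        return "no CDS"
    if cds_n is None:
        return "no normal CDS"
    if cds_t is None:
        return "no tumor CDS"
    return "no protein affected" if cds_t == cds_n else "protein affected"


def switch_occurrence_matrix(
    switches: pd.DataFrame,
    dataset: ExpressionDataset,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Binary switch x sample matrix: 1 iff the sample fulfils the tumor rule.

    The tumor-orientation rule holds when the tumor isoform is expressed at
    or above the normal isoform (ties take the rule's "else" branch).
    """
    samples = list(samples) if samples is not None else dataset.sample_ids
    tpm = dataset.abundance[samples]
    data = {}
    for row in switches.itertuples(index=False):
        t = tpm.loc[row.tumor_isoform].to_numpy(dtype=float)
        n = tpm.loc[row.normal_isoform].to_numpy(dtype=float)
        data[f"{row.gene}:{row.tumor_isoform}|{row.normal_isoform}"] = (t >= n).astype(int)
    return pd.DataFrame(data, index=samples).T
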