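"""Core data containers: transcript expression, annotation and mutation tables.

The central object is :class:`ExpressionDataset`, a transcript-by-sample
abundance matrix (TPM) together with a transcript->gene map and a two-class
sample labelling (class1, the "normal"-like reference class, and class2, the
"tumor"-like class).  Relative isoform abundance (PSI, "percent spliced in")
is derived lazily from the TPM matrix: for each transcript, its TPM divided
by the summed TPM of all transcripts of its gene in that sample.

All downstream scoring is rank-based within samples, so no between-sample
normalisation is performed beyond the TPM definition itself; any strictly
monotone per-sample transform of the abundances leaves every score unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "MutationTable",
    "TranscriptStructure",
    "MUTATION_CLASSES",
    "PROTEIN_AFFECTING_CLASSES",
    "compute_tpm",
    "compute_psi",
    "filter_genes",
]

#: Somatic mutation classes accepted in mutation tables.
MUTATION_CLASSES = frozenset(
    {"nonsense", "missense", "frameshift", "indel", "synonymous", "splice-site", "RNA"}
)

#: Mutation classes that change the encoded protein sequence.
PROTEIN_AFFECTING_CLASSES = frozenset({"nonsense", "missense", "frameshift", "indel"})


def compute_tpm(counts: pd.DataFrame, lengths: Mapping[str, float]) -> pd.DataFrame:
    """Convert estimated read counts to transcripts per million.

    TPM_t = 1e6 * (c_t / l_t) / sum_u (c_u / l_u), per sample.

    Parameters
    ----------
    counts : DataFrame, transcripts x samples, non-negative.
    lengths : mapping transcript id -> effective length in nt (> 0).

    An all-zero sample column yields an all-zero TPM column with a warning.
    """
    missing = [t for t in counts.index if t not in lengths]
    if missing:
        raise ValueError(f"missing transcript length for: {missing[:5]}")
    lens = np.asarray([float(lengths[t]) for t in counts.index])
    if np.any(lens <= 0):
        raise ValueError("transcript lengths must be positive")
    c = counts.to_numpy(dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    rate = c / lens[:, None]
    denom = rate.sum(axis=0)
    zero_cols = denom == 0
    if zero_cols.any():
        warnings.warn(
            f"{int(zero_cols.sum())} sample(s) have zero total counts; "
            "their TPM columns are all zero",
            stacklevel=2,
        )
        denom = np.where(zero_cols, 1.0, denom)
    tpm = 1e6 * rate / denom
    tpm[:, zero_cols] = 0.0
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)


def compute_psi(tpm: pd.DataFrame, gene_of: Mapping[str, str]) -> pd.DataFrame:
    """Relative isoform abundance per gene: TPM_t / sum of its gene's TPMs.

    Entries of a gene whose total TPM in a sample is zero are NaN (missing),
    never 0: a silent gene carries no isoform-usage information.
    """
    x = tpm.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("TPM must be non-negative")
    genes = pd.Index([gene_of[t] for t in tpm.index], name="gene")
    totals = pd.DataFrame(x, index=genes, columns=tpm.columns).groupby(level=0).sum()
    denom = totals.reindex(genes).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(denom > 0, x / np.where(denom > 0, denom, 1.0), np.nan)
    return pd.DataFrame(psi, index=tpm.index, columns=tpm.columns)


@dataclass
class TranscriptStructure:
    """Genomic structure of one transcript: sorted, non-overlapping exons.

    Coordinates are GTF-style, 1-based and inclusive on both ends.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        exons = sorted((int(a), int(b)) for a, b in self.exons)
        for a, b in exons:
            if a > b:
                raise ValueError(f"{self.transcript_id}: exon start {a} > end {b}")
        for (_, b0), (a1, _) in zip(exons, exons[1:]):
            if a1 <= b0:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        self.exons = exons

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(b - a + 1 for a, b in self.exons)


@dataclass
class MutationTable:
    """Minimal MAF-like somatic mutation table.

    Each record: (sample, chrom, start, end, mutation class, gene or None),
    coordinates 1-based inclusive.
    """

    records: pd.DataFrame

    REQUIRED = ("sample", "chrom", "start", "end", "mut_class")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"mutation table missing column {col!r}")
        if "gene" not in df.columns:
            df["gene"] = None
        df = df.reset_index(drop=True)
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["start"] > df["end"]).any():
            raise ValueError("mutation start > end")
        bad = set(df["mut_class"]) - MUTATION_CLASSES
        if bad:
            raise ValueError(f"unknown mutation class(es): {sorted(bad)}")
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    @property
    def samples(self) -> set[str]:
        return set(self.records["sample"])


class ExpressionDataset:
    """Transcript x sample TPM matrix with gene map and two-class labels.

    Parameters
    ----------
    abundance : DataFrame, transcripts x samples, TPM, non-negative.
    gene_of : mapping transcript -> gene id (every transcript exactly one gene).
    class_of : mapping sample -> class label; exactly two distinct labels.
    class1, class2 : which label plays the reference ("normal") and the
        contrast ("tumor") role.  If omitted and the labels are literally
        {"normal", "tumor"}, that assignment is used; otherwise labels are
        taken in sorted order.
    pairing : optional mapping patient -> (class1 sample, class2 sample).
    symbol_of : optional mapping gene -> gene symbol (empty/None = no symbol).
    """

    def __init__(
        self,
        abundance: pd.DataFrame,
        gene_of: Mapping[str, str],
        class_of: Mapping[str, str],
        *,
        class1: str | None = None,
        class2: str | None = None,
        pairing: Mapping[str, tuple[str, str]] | None = None,
        symbol_of: Mapping[str, str | None] | None = None,
    ) -> None:
        if abundance.index.duplicated().any():
            raise ValueError("duplicate transcript ids")
        if abundance.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        x = abundance.to_numpy(dtype=float)
        if np.any(x < 0) or np.any(~np.isfinite(x)):
            raise ValueError("abundance must be finite and non-negative")
        missing = [t for t in abundance.index if t not in gene_of]
        if missing:
            raise ValueError(f"transcripts without gene mapping: {missing[:5]}")
        missing = [s for s in abundance.columns if s not in class_of]
        if missing:
            raise ValueError(f"samples without class label: {missing[:5]}")

        self.abundance = abundance.astype(float)
        self.gene_of = pd.Series({t: gene_of[t] for t in abundance.index}, name="gene")
        self.class_of = pd.Series({s: class_of[s] for s in abundance.columns}, name="class")
        labels = sorted(set(self.class_of))
        if len(labels) != 2:
            raise ValueError(f"expected exactly 2 class labels, got {labels}")
        if class1 is None and class2 is None:
            if set(labels) == {"normal", "tumor"}:
                class1, class2 = "normal", "tumor"
            else:
                class1, class2 = labels
        elif class1 is None or class2 is None:
            (other,) = set(labels) - {class1 or class2}
            class1 = class1 or other
            class2 = class2 or other
        if {class1, class2} != set(labels):
            raise ValueError(f"class1/class2 {class1, class2} do not match labels {labels}")
        self.class1 = class1
        self.class2 = class2
        self.symbol_of = dict(symbol_of) if symbol_of is not None else None

        self.pairing: dict[str, tuple[str, str]] | None = None
        if pairing is not None:
            for patient, (s1, s2) in pairing.items():
                if s1 not in self.class_of.index or s2 not in self.class_of.index:
                    raise ValueError(f"pairing for {patient!r} names unknown samples")
                if self.class_of[s1] != class1 or self.class_of[s2] != class2:
                    raise ValueError(
                        f"pairing for {patient!r} must be (class1 sample, class2 sample)"
                    )
            self.pairing = {p: tuple(v) for p, v in pairing.items()}

        self._psi: pd.DataFrame | None = None

    # -- basic views -------------------------------------------------------

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[1]

    def samples_of_class(self, label: str) -> list[str]:
        return [s for s in self.sample_ids if self.class_of[s] == label]

    @property
    def psi(self) -> pd.DataFrame:
        """PSI matrix (lazily computed, cached); NaN where the gene is silent."""
        if self._psi is None:
            self._psi = compute_psi(self.abundance, self.gene_of)
        return self._psi

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.gene_of:
            seen.setdefault(g, None)
        return list(seen)

    def transcripts_of_gene(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for t, g in self.gene_of.items():
            out.setdefault(g, []).append(t)
        return out

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        lengths: Mapping[str, float],
        gene_of: Mapping[str, str],
        class_of: Mapping[str, str],
        **kwargs,
    ) -> "ExpressionDataset":
        """Build from estimated read counts + transcript lengths (TPM computed)."""
        return cls(compute_tpm(counts, lengths), gene_of, class_of, **kwargs)

    # -- manipulation ------------------------------------------------------

    def subset_samples(self, samples: Sequence[str], class_of=None) -> "ExpressionDataset":
        """Dataset restricted to `samples` (pairing dropped unless intact)."""
        cls_map = dict(self.class_of) if class_of is None else dict(class_of)
        pairing = None
        if self.pairing and class_of is None:
            kept = {
                p: v for p, v in self.pairing.items() if v[0] in samples and v[1] in samples
            }
            pairing = kept or None
        return ExpressionDataset(
            self.abundance.loc[:, list(samples)],
            self.gene_of,
            {s: cls_map[s] for s in samples},
            class1=self.class1 if class_of is None else None,
            class2=self.class2 if class_of is None else None,
            pairing=pairing,
            symbol_of=self.symbol_of,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<ExpressionDataset {len(self.transcript_ids)} transcripts, "
            f"{len(self.genes)} genes, {self.n_samples} samples "
            f"({self.class1} vs {self.class2})>"
        )


def filter_genes(dataset: ExpressionDataset) -> ExpressionDataset:
    """Drop single-isoform genes and genes lacking an accepted gene symbol.

    The symbol filter only applies when symbols were supplied; without a
    symbol column the filter is skipped with a warning (mirroring the HUGO-id
    filter applied to annotated data).
    """
    counts = dataset.gene_of.value_counts()
    multi = set(counts[counts >= 2].index)
    keep_genes = multi
    if dataset.symbol_of is None:
        warnings.warn("no gene symbols supplied; skipping the symbol filter", stacklevel=2)
    else:
        keep_genes = {
            g for g in multi if dataset.symbol_of.get(g) not in (None, "", "NA")
        }
    keep = [t for t in dataset.transcript_ids if dataset.gene_of[t] in keep_genes]
    if not keep:
        warnings.warn("gene filtering removed every gene", stacklevel=2)
    return ExpressionDataset(
        dataset.abundance.loc[keep],
        dataset.gene_of[keep],
        dict(dataset.class_of),
        class1=dataset.class1,
        class2=dataset.class2,
        pairing=dataset.pairing,
        symbol_of=dataset.symbol_of,
    )
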