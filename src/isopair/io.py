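"""Readers and writers for the plain-text dialects the tool consumes.

Expression: TSV, header row of sample ids; column 1 = transcript id,
column 2 = gene id, optional column 3 = gene symbol; values are counts or
TPM.  Labels: TSV with columns sample, class and optional patient (for
tumor/normal pairing).  Lengths: two-column TSV.  Annotation: GTF exon
features.  Mutations: minimal MAF-derived TSV (sample, chrom, start, end,
class, gene).  All coordinates 1-based inclusive.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd

from .datasets import (
    ExpressionDataset,
    MutationTable,
    TranscriptStructure,
    compute_tpm,
)

__all__ = [
    "read_expression",
    "read_lengths",
    "read_labels",
    "read_gtf",
    "read_mutations",
    "read_dataset",
    "write_expression",
    "write_labels",
    "write_mutations",
    "write_gtf",
    "write_switch_gff",
]


def read_expression(path: str) -> tuple[pd.DataFrame, dict, dict | None]:
    """Read an expression TSV -> (matrix, gene_of, symbol_of or None)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str, 1: str})
    cols = list(df.columns)
    if len(cols) < 3:
        raise ValueError(f"{path}: expected transcript, gene and >=1 sample column")
    has_symbol = cols[2].lower() in {"symbol", "gene_symbol"}
    df = df.set_index(cols[0])
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate transcript id {dup!r}")
    gene_of = df[cols[1]].astype(str).to_dict()
    symbol_of = None
    first_sample = 2
    if has_symbol:
        sym = df[cols[2]]
        symbol_of = {
            gene_of[t]: (None if pd.isna(v) or v == "" else str(v))
            for t, v in sym.items()
        }
        first_sample = 3
    matrix = df[cols[first_sample:]].astype(float)
    if matrix.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in header")
    return matrix, gene_of, symbol_of


def read_lengths(path: str) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (transcript, length)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def read_labels(path: str) -> tuple[dict, dict | None]:
    """Read a label TSV -> (class_of, pairing or None).

    Requires exactly two distinct class labels.  When a patient column is
    present, every patient listed with both one class1 and one class2 sample
    contributes a pair.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "sample" not in cols or "class" not in cols:
        raise ValueError(f"{path}: expected columns 'sample' and 'class'")
    if df[cols["sample"]].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    class_of = dict(zip(df[cols["sample"]], df[cols["class"]]))
    labels = sorted(set(class_of.values()))
    if len(labels) != 2:
        raise ValueError(f"{path}: expected exactly 2 classes, found {labels}")
    pairing = None
    if "patient" in cols:
        c1, c2 = ("normal", "tumor") if set(labels) == {"normal", "tumor"} else labels
        pairing = {}
        for patient, grp in df.dropna(subset=[cols["patient"]]).groupby(cols["patient"]):
            by_class = {class_of[s]: s for s in grp[cols["sample"]]}
            if c1 in by_class and c2 in by_class and len(grp) == 2:
                pairing[str(patient)] = (by_class[c1], by_class[c2])
        pairing = pairing or None
    return class_of, pairing


def read_gtf(path: str) -> dict[str, TranscriptStructure]:
    """Parse GTF exon features into TranscriptStructure objects (1-based)."""
    import pyranges

    gr = pyranges.read_gtf(path)
    df = gr.df if hasattr(gr, "df") else pd.DataFrame(gr)
    df = df[df["Feature"] == "exon"]
    out: dict[str, TranscriptStructure] = {}
    for tid, grp in df.groupby("transcript_id", sort=False):
        chroms = set(grp["Chromosome"].astype(str))
        if len(chroms) != 1:
            raise ValueError(f"{path}: transcript {tid} spans multiple chromosomes")
        strand = str(grp["Strand"].iloc[0]) if "Strand" in grp else "+"
        # pyranges stores 0-based half-open intervals; convert to 1-based inclusive
        exons = [(int(s) + 1, int(e)) for s, e in zip(grp["Start"], grp["End"])]
        out[str(tid)] = TranscriptStructure(str(tid), chroms.pop(), strand, exons)
    return out


def read_mutations(path: str) -> MutationTable:
    df = pd.read_csv(path, sep="\t", header=0, dtype={"sample": str, "chrom": str})
    df = df.rename(columns={c: c.lower() for c in df.columns})
    if "class" in df.columns and "mut_class" not in df.columns:
        df = df.rename(columns={"class": "mut_class"})
    return MutationTable(df)


def read_dataset(
    expression: str,
    labels: str,
    *,
    units: str = "tpm",
    lengths: str | None = None,
) -> ExpressionDataset:
    """Assemble an ExpressionDataset from an expression and a label file.

    ``units="counts"`` requires a lengths file; TPM is then computed.  PSI is
    always recomputed internally from TPM.
    """
    matrix, gene_of, symbol_of = read_expression(expression)
    class_of, pairing = read_labels(labels)
    if units == "counts":
        if lengths is None:
            raise ValueError("units='counts' requires a transcript lengths file")
        matrix = compute_tpm(matrix, read_lengths(lengths))
    elif units != "tpm":
        raise ValueError(f"units must be 'tpm' or 'counts', got {units!r}")
    return ExpressionDataset(matrix, gene_of, class_of, pairing=pairing, symbol_of=symbol_of)


# -- writers ---------------------------------------------------------------


def write_expression(dataset: ExpressionDataset, path: str) -> None:
    out = dataset.abundance.copy()
    out.insert(0, "gene", [dataset.gene_of[t] for t in out.index])
    if dataset.symbol_of is not None:
        out.insert(1, "symbol", [dataset.symbol_of.get(g, "") for g in out["gene"]])
    out.index.name = "transcript"
    out.to_csv(path, sep="\t", float_format="%.6g")


def write_labels(dataset: ExpressionDataset, path: str) -> None:
    patient_of = {}
    if dataset.pairing:
        for p, (s1, s2) in dataset.pairing.items():
            patient_of[s1] = p
            patient_of[s2] = p
    rows = [
        {"sample": s, "class": dataset.class_of[s], "patient": patient_of.get(s, "")}
        for s in dataset.sample_ids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_mutations(mutations: MutationTable, path: str) -> None:
    df = mutations.records.copy()
    df["gene"] = df["gene"].fillna("")
    df.to_csv(path, sep="\t", index=False)


def _gtf_line(chrom, source, feature, start, end, strand, attrs) -> str:
    attr = " ".join(f'{k} "{v}";' for k, v in attrs)
    return f"{chrom}\t{source}\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t{attr}"


def write_gtf(
    structures: Mapping[str, TranscriptStructure],
    gene_of: Mapping[str, str],
    path: str,
    source: str = "isopair",
) -> None:
    with open(path, "w") as fh:
        for tid, ts in structures.items():
            attrs = [("gene_id", gene_of.get(tid, tid)), ("transcript_id", tid)]
            for a, b in ts.exons:
                fh.write(_gtf_line(ts.chrom, source, "exon", a, b, ts.strand, attrs) + "\n")


def write_switch_gff(
    switches: pd.DataFrame,
    structures: Mapping[str, TranscriptStructure],
    path: str,
) -> None:
    """Export both isoforms of each switch as GFF exon features.

    Each exon line carries the gene, the transcript and its role in the
    switch (tumor_isoform / normal_isoform).
    """
    with open(path, "w") as fh:
        for _, row in switches.iterrows():
            for role in ("tumor_isoform", "normal_isoform"):
                tid = row[role]
                if tid not in structures:
                    raise KeyError(f"no structure for transcript {tid!r}")
                ts = structures[tid]
                attrs = [("gene_id", row["gene"]), ("transcript_id", tid), ("role", role)]
                for a, b in ts.exons:
                    fh.write(_gtf_line(ts.chrom, "isopair", "exon", a, b, ts.strand, attrs) + "\n")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
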