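"""Synthetic paired two-class transcript expression with planted switches.

The generator emulates the statistical structure the rank-reversal method
assumes: a paired tumor/normal design, per-gene isoform abundance profiles
that are identical across classes for null genes, and, for planted switch
genes, a swap of the two designated isoforms' mean abundances in each tumor
sample independently with probability = penetrance.  Swapping means (rather
than shifting them) keeps the gene's total expression constant, so planted
signal is purely a splicing change, never an expression change.

Multiplicative log-normal noise and Bernoulli zero-inflation are applied to
the means, after which each sample is renormalised to 1e6 (TPM).  The noise
produces the non-strictly-monotone rankings (double zeros, ties) that the
strict-tie S1 policy exists for.

Optionally, tumor samples acquire somatic mutations: planted switch genes
follow a two-rate model (P(mut | switch present in the sample) vs
P(mut | absent)), all other genes a background rate.  A subtype mode
restricts a subset of planted switches to one tumor subtype.

Everything is deterministic given the seed, and a truth table records the
planted pairs, the per-sample switch realisations and the mutation flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, MutationTable, TranscriptStructure
from . import io as _io

__all__ = ["SimulationConfig", "TruthTable", "simulate", "write_fixture"]

_MUT_CLASSES = ("nonsense", "missense", "frameshift", "indel", "synonymous", "splice-site", "RNA")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults describe a desk-scale paired tumor/normal cohort: 1000 genes
    with 2-5 isoforms, 30 patient pairs plus 30 unpaired tumors, 50 planted
    switches at penetrance 0.95, log-normal gene abundance around 100 TPM
    with a clearly dominant isoform, multiplicative noise sigma 0.5 and 5%
    zero-inflation.
    """

    n_genes: int = 1000
    isoforms_per_gene: tuple[int, int] = (2, 5)
    n_patient_pairs: int = 30
    n_unpaired_tumor: int = 30
    n_switch_genes: int = 50
    penetrance: float = 0.95
    base_scale: float = 100.0  # median gene-level TPM before renormalisation
    gene_abundance_sigma: float = 1.0  # lognormal sigma of gene abundance
    dominant_fraction: tuple[float, float] = (0.6, 0.85)  # dominant isoform share
    minor_ratio: tuple[float, float] = (0.15, 0.4)  # designated minor / dominant
    dispersion: float = 0.5  # lognormal noise sigma
    zero_inflation: float = 0.05
    # subtype structure (optional): tumor samples get one of these labels and
    # the last n_subtype_switch_genes planted switches apply only in
    # subtype_target samples
    subtype_labels: tuple[str, ...] | None = None
    n_subtype_switch_genes: int = 0
    subtype_target: str | None = None
    # mutation model (optional): two-rate model on planted switch genes and
    # a background per-gene-per-sample rate elsewhere
    p_mut_switch: float | None = None
    p_mut_noswitch: float | None = None
    background_mutation_rate: float = 0.0
    seed: int | None = None

    def validate(self) -> None:
        if self.n_switch_genes > self.n_genes:
            raise ValueError("n_switch_genes must be <= n_genes")
        lo, hi = self.isoforms_per_gene
        if lo < 2 or hi < lo:
            raise ValueError("isoforms_per_gene must satisfy 2 <= lo <= hi")
        for name in ("penetrance", "zero_inflation", "background_mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("p_mut_switch", "p_mut_noswitch"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_subtype_switch_genes:
            if not self.subtype_labels or self.subtype_target not in self.subtype_labels:
                raise ValueError("subtype switches need subtype_labels and a valid subtype_target")
            if self.n_subtype_switch_genes > self.n_switch_genes:
                raise ValueError("n_subtype_switch_genes must be <= n_switch_genes")


@dataclass
class TruthTable:
    """Planted ground truth: per-gene switch status and per-sample realisations."""

    genes: pd.DataFrame  # gene, is_switch, tumor_isoform, normal_isoform, subtype_only
    switch_flags: pd.DataFrame  # switch genes x tumor samples, 0/1
    mutation_flags: pd.DataFrame  # genes-with-mutations x tumor samples, 0/1

    @property
    def switch_genes(self) -> list[str]:
        return list(self.genes.loc[self.genes["is_switch"], "gene"])

    def planted_pairs(self) -> set[tuple[str, str, str]]:
        sub = self.genes[self.genes["is_switch"]]
        return {
            (r.gene, r.tumor_isoform, r.normal_isoform) for r in sub.itertuples(index=False)
        }


def _make_structures(
    gene_ids: Sequence[str],
    tx_of_gene: dict[str, list[str]],
    lengths: dict[str, int],
    rng: np.random.Generator,
) -> dict[str, TranscriptStructure]:
    """Lay genes along chr1 with gaps; two exons per transcript, offset starts."""
    structures: dict[str, TranscriptStructure] = {}
    cursor = 1000
    for g in gene_ids:
        txs = tx_of_gene[g]
        span_len = max(lengths[t] for t in txs) * 2 + 200
        for k, t in enumerate(txs):
            ln = lengths[t]
            e1 = ln // 2
            e2 = ln - e1
            start = cursor + k * 50  # offset so transcript spans differ
            exon1 = (start, start + e1 - 1)
            exon2 = (start + span_len - e2, start + span_len - 1)
            structures[t] = TranscriptStructure(t, "chr1", "+", [exon1, exon2])
        cursor += span_len + 50 * len(txs) + 5000  # intergenic gap
    return structures


def simulate(
    config: SimulationConfig, seed: int | None = None
) -> tuple[ExpressionDataset, MutationTable, dict[str, TranscriptStructure], TruthTable]:
    """Generate (dataset, mutations, structures, truth) under ``config``.

    ``seed`` overrides ``config.seed``.  Identical seeds give identical
    output, byte for byte.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    gene_ids = [f"G{i:05d}" for i in range(1, config.n_genes + 1)]
    lo, hi = config.isoforms_per_gene
    n_iso = rng.integers(lo, hi + 1, size=config.n_genes)
    tx_of_gene: dict[str, list[str]] = {}
    transcript_ids: list[str] = []
    gene_of: dict[str, str] = {}
    for g, k in zip(gene_ids, n_iso):
        txs = [f"{g}.t{j}" for j in range(1, k + 1)]
        tx_of_gene[g] = txs
        transcript_ids += txs
        for t in txs:
            gene_of[t] = g
    lengths = {t: int(rng.integers(500, 5001)) for t in transcript_ids}

    # sample layout: paired normals, paired tumors, unpaired tumors
    patients = [f"P{i:03d}" for i in range(1, config.n_patient_pairs + 1)]
    normal_samples = [f"{p}_N" for p in patients]
    tumor_paired = [f"{p}_T" for p in patients]
    tumor_unpaired = [f"U{i:03d}_T" for i in range(1, config.n_unpaired_tumor + 1)]
    tumor_samples = tumor_paired + tumor_unpaired
    samples = normal_samples + tumor_samples
    class_of = {s: ("normal" if s.endswith("_N") else "tumor") for s in samples}
    pairing = {p: (f"{p}_N", f"{p}_T") for p in patients}

    subtype_of: dict[str, str] = {}
    if config.subtype_labels:
        labs = list(config.subtype_labels)
        assigned = rng.integers(0, len(labs), size=len(tumor_samples))
        subtype_of = {s: labs[a] for s, a in zip(tumor_samples, assigned)}

    # per-gene isoform mean profiles (shared by both classes for null genes)
    gene_abund = config.base_scale * rng.lognormal(
        mean=0.0, sigma=config.gene_abundance_sigma, size=config.n_genes
    )
    switch_genes = gene_ids[: config.n_switch_genes]
    subtype_only = set(
        switch_genes[config.n_switch_genes - config.n_subtype_switch_genes :]
        if config.n_subtype_switch_genes
        else []
    )
    base_means: dict[str, np.ndarray] = {}
    planted: dict[str, tuple[str, str]] = {}  # gene -> (tumor_iso, normal_iso)
    for gi, g in enumerate(gene_ids):
        k = len(tx_of_gene[g])
        if g in switch_genes:
            # dominant isoform t1 is the normal isoform; the designated minor
            # t2 takes over in tumor; any remaining isoforms stay below t2 so
            # the planted pair are the gene's two most abundant isoforms
            w = np.empty(k)
            w[0] = rng.uniform(*config.dominant_fraction)
            w[1] = w[0] * rng.uniform(*config.minor_ratio)
            if k > 2:
                w[2:] = w[1] * rng.uniform(0.1, 0.8, size=k - 2)
            props = w / w.sum()
            planted[g] = (tx_of_gene[g][1], tx_of_gene[g][0])
        else:
            props = rng.dirichlet(np.ones(k))
        base_means[g] = gene_abund[gi] * props

    n_s = len(samples)
    means = np.vstack([base_means[gene_of[t]][tx_of_gene[gene_of[t]].index(t)] * np.ones(n_s) for t in transcript_ids])
    tx_index = {t: i for i, t in enumerate(transcript_ids)}

    # plant the reversals: swap the designated isoform means per tumor sample
    flag_rows = {}
    tumor_pos = {s: samples.index(s) for s in tumor_samples}
    for g in switch_genes:
        t_iso, n_iso_id = planted[g]
        eligible = {
            s
            for s in tumor_samples
            if g not in subtype_only or subtype_of.get(s) == config.subtype_target
        }
        hits = rng.random(len(tumor_samples)) < config.penetrance
        flags = {}
        for s, hit in zip(tumor_samples, hits):
            on = bool(hit) and s in eligible
            flags[s] = int(on)
            if on:
                i, j = tx_index[t_iso], tx_index[n_iso_id]
                col = tumor_pos[s]
                means[i, col], means[j, col] = means[j, col], means[i, col]
        flag_rows[g] = flags
    switch_flags = (
        pd.DataFrame(flag_rows).T.reindex(columns=tumor_samples).fillna(0).astype(int)
        if flag_rows
        else pd.DataFrame(columns=tumor_samples, dtype=int)
    )

    # noise -> zero-inflation -> TPM renormalisation
    x = means.copy()
    if config.dispersion > 0:
        x = x * rng.lognormal(0.0, config.dispersion, size=x.shape)
    if config.zero_inflation > 0:
        x = np.where(rng.random(x.shape) < config.zero_inflation, 0.0, x)
    totals = x.sum(axis=0)
    totals[totals == 0] = 1.0
    x = 1e6 * x / totals

    abundance = pd.DataFrame(x, index=transcript_ids, columns=samples)
    symbol_of = {g: g for g in gene_ids}  # every simulated gene carries a symbol
    dataset = ExpressionDataset(
        abundance,
        gene_of,
        class_of,
        class1="normal",
        class2="tumor",
        pairing=pairing,
        symbol_of=symbol_of,
    )
    dataset.subtype_of = subtype_of  # attached for the subtype workflow

    structures = _make_structures(gene_ids, tx_of_gene, lengths, rng)

    # mutations
    mut_records = []
    mut_flag_rows: dict[str, dict[str, int]] = {}
    two_rate = config.p_mut_switch is not None and config.p_mut_noswitch is not None
    if two_rate or config.background_mutation_rate > 0:
        for g in gene_ids:
            spans = [structures[t].span for t in tx_of_gene[g]]
            g_lo = min(a for a, _ in spans)
            g_hi = max(b for _, b in spans)
            flags = {}
            for s in tumor_samples:
                if g in planted and two_rate:
                    p = (
                        config.p_mut_switch
                        if switch_flags.loc[g, s] == 1
                        else config.p_mut_noswitch
                    )
                else:
                    p = config.background_mutation_rate
                hit = rng.random() < p
                flags[s] = int(hit)
                if hit:
                    pos = int(rng.integers(g_lo, g_hi + 1))
                    mut_records.append(
                        {
                            "sample": s,
                            "chrom": "chr1",
                            "start": pos,
                            "end": pos,
                            "mut_class": _MUT_CLASSES[rng.integers(0, len(_MUT_CLASSES))],
                            "gene": g,
                        }
                    )
            if any(flags.values()):
                mut_flag_rows[g] = flags
    mutations = MutationTable(
        pd.DataFrame(mut_records, columns=["sample", "chrom", "start", "end", "mut_class", "gene"])
    )
    mutation_flags = (
        pd.DataFrame(mut_flag_rows).T.reindex(columns=tumor_samples).fillna(0).astype(int)
        if mut_flag_rows
        else pd.DataFrame(columns=tumor_samples, dtype=int)
    )

    truth_genes = pd.DataFrame(
        {
            "gene": gene_ids,
            "is_switch": [g in planted for g in gene_ids],
            "tumor_isoform": [planted.get(g, ("", ""))[0] for g in gene_ids],
            "normal_isoform": [planted.get(g, ("", ""))[1] for g in gene_ids],
            "subtype_only": [g in subtype_only for g in gene_ids],
        }
    )
    truth = TruthTable(genes=truth_genes, switch_flags=switch_flags, mutation_flags=mutation_flags)
    return dataset, mutations, structures, truth


def write_fixture(
    dataset: ExpressionDataset,
    mutations: MutationTable,
    structures: dict[str, TranscriptStructure],
    truth: TruthTable,
    out_dir: str,
) -> dict[str, str]:
    """Write the full file set (TSV/GTF dialects) for a simulated dataset."""
    _io.ensure_dir(out_dir)
    import os

    paths = {
        "expression": os.path.join(out_dir, "expression.tsv"),
        "labels": os.path.join(out_dir, "labels.tsv"),
        "annotation": os.path.join(out_dir, "annotation.gtf"),
        "mutations": os.path.join(out_dir, "mutations.tsv"),
        "truth_genes": os.path.join(out_dir, "truth_genes.tsv"),
        "truth_switch_flags": os.path.join(out_dir, "truth_switch_flags.tsv"),
    }
    _io.write_expression(dataset, paths["expression"])
    _io.write_labels(dataset, paths["labels"])
    _io.write_gtf(structures, dict(dataset.gene_of), paths["annotation"])
    _io.write_mutations(mutations, paths["mutations"])
    truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    truth.switch_flags.to_csv(paths["truth_switch_flags"], sep="\t", index_label="gene")
    return paths
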