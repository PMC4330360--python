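from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from isopair.datasets import ExpressionDataset
from isopair.simulate import SimulationConfig, simulate


def make_dataset(matrix, gene_of, labels, pairing=None, **kw):
    """Small ExpressionDataset from plain dicts/lists of per-sample values."""
    samples = [f"s{i}" for i in range(len(next(iter(matrix.values()))))]
    df = pd.DataFrame({s: [matrix[t][i] for t in matrix] for i, s in enumerate(samples)},
                      index=list(matrix))
    class_of = dict(zip(samples, labels))
    return ExpressionDataset(df, gene_of, class_of, pairing=pairing, **kw)


def random_instance(rng, n_genes=None, max_iso=5, n_samples=None):
    """A random small instance for oracle-equivalence checks.

    Integer-valued expression with frequent ties and zeros, mimicking the
    tie structure of zero-inflated TPM data.
    """
    n_genes = n_genes or int(rng.integers(1, 11))
    n_samples = n_samples or int(rng.integers(4, 13))
    n1 = int(rng.integers(1, n_samples))
    labels = ["normal"] * n1 + ["tumor"] * (n_samples - n1)
    expression = {}
    gene_of = {}
    for g in range(n_genes):
        k = int(rng.integers(2, max_iso + 1))
        for t in range(k):
            tid = f"g{g}.t{t}"
            vals = rng.integers(0, 6, size=n_samples).astype(float)
            expression[tid] = list(vals)
            gene_of[tid] = f"g{g}"
    return expression, gene_of, labels


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated dataset with planted switches, reused across tests."""
    cfg = SimulationConfig(
        n_genes=120, n_switch_genes=6, n_patient_pairs=12, n_unpaired_tumor=8,
        p_mut_switch=0.5, p_mut_noswitch=0.02, background_mutation_rate=0.02,
    )
    return simulate(cfg, seed=7)


@pytest.fixture()
def perfect_dataset():
    """Two genes; gene ga reverses perfectly, gene gb is constant-order."""
    matrix = {
        "ga.t1": [1, 2, 1, 9, 8, 9],   # tumor isoform of ga
        "ga.t2": [9, 8, 9, 1, 2, 1],   # normal isoform of ga
        "gb.t1": [5, 6, 5, 6, 5, 6],
        "gb.t2": [1, 2, 1, 2, 1, 2],
    }
    gene_of = {t: t.split(".")[0] for t in matrix}
    labels = ["normal"] * 3 + ["tumor"] * 3
    pairing = {f"p{i}": (f"s{i}", f"s{i+3}") for i in range(3)}
    return make_dataset(matrix, gene_of, labels, pairing=pairing)
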