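# isopair

Rank-based detection of recurrent alternative-splicing isoform changes and
isoform switches between two sample classes (e.g. tumor vs matched normal)
from transcript-level RNA-seq expression.

## Who this is for

Cancer transcriptomics groups (and anyone comparing two conditions at the
transcript level) who want classifiers and candidate functional changes that
are robust to the variability of isoform quantification across patients.
Because every statistic depends only on the *within-sample ordering* of
transcript expression, the results are invariant to any monotone per-sample
transform — no between-sample normalisation is needed or performed.

## The method

For each gene *g*, every pair of isoforms *(I_g,i, I_g,j)* is scored by how
consistently their relative expression order reverses between classes C1
("normal") and C2 ("tumor"):

    S1(I_g,i, I_g,j) = P(I_g,i > I_g,j | C1) + P(I_g,i < I_g,j | C2) − 1

with the frequencies taken over the samples of each class using **strict**
inequalities: exactly tied samples (common with zero-inflated RNA-seq
counts) stay in the denominator but count toward neither order, penalising
unexpressed pairs. S1 = 1 is a perfect reversal. Ties in S1 are broken by
S2, the absolute between-class difference of the mean within-sample rank
difference of the two isoforms. One pair per gene is listed, and each
listed pair defines a classification rule

    tumor_isoform < normal_isoform  ⇒  normal,   else  ⇒  tumor

whose discriminative power is summarised by the information gain (IG, bits)
of its vote. The workflow then:

1. **Model selection** — leave-one-patient-pair-out cross-validation; the
   minimal classifier takes the top *k*\_opt pairs of the global ranking,
   where *k*\_opt is the smallest odd *k* with the highest mean CV accuracy;
   classification of a sample is by simple majority vote of the *k* rules.
2. **Significance** — a max-statistic permutation null: class labels are
   shuffled (1000 permutations by default), the ranking is recomputed, and
   the top S1 and top IG recorded; a pair is significant only if its S1
   *and* IG strictly exceed the maxima over all permutations (family-wise
   error control).
3. **Isoform switches** — significant pairs with S1 > 0.5 (a reversal in
   >75% of samples), Spearman anti-correlation of the two isoforms' PSI
   values < −0.8 across the paired samples, and mean expression > 1 TPM per
   isoform in at least one class: changes in the *dominant* isoform, the
   candidates most likely to matter functionally.
4. **Mutation association** — per switch: Jaccard index J = |M∩S|/|M∪S| of
   the mutated (M) and switch-carrying (S) sample sets, plug-in mutual
   information, the mutual-exclusion score mx = 2·min(n10, n01)/N, each with
   a z-score against the 100 genes nearest in median isoform length, plus a
   Mann–Whitney test of ΔPSI between mutated and non-mutated tumor samples
   (Benjamini–Hochberg corrected).

A one-vs-pool subsampling mode finds subtype-specific changes, and a
gene-level mode (classic top-scoring-pairs on summed transcript TPM) is
included for comparison.

## Worked example

```python
from isopair import IsoformPairModel, SimulationConfig, simulate

cfg = SimulationConfig(n_genes=300, n_switch_genes=10,
                       n_patient_pairs=20, n_unpaired_tumor=10)
dataset, mutations, structures, truth = simulate(cfg, seed=42)

model = IsoformPairModel(dataset)
res = model.fit(k_max=7, n_perm=500, seed=0)
print(res.summary())
```

```
Isoform-pair reversal model
============================================================
transcripts: 1048   genes: 300   samples: 50 (normal vs tumor)
tie policy: strict   seed: 0

listed pairs:        300
permutations:        500
S1 threshold (max):  0.6000
IG threshold (max):  0.3119
significant pairs:   9
isoform switches:    8

cross-validation mean accuracy  k=1: 0.975, k=3: 1.000, k=5: 1.000, k=7: 1.000
k_opt: 3

top pairs (gene, tumor_isoform, normal_isoform, S1, S2, IG):
    1 G00008 G00008.t2 G00008.t1 0.9667 540.700 0.8549
    2 G00005 G00005.t2 G00005.t1 0.9000 665.400 0.7140
    3 G00002 G00002.t2 G00002.t1 0.8333 694.392 0.5713
    4 G00003 G00003.t2 G00003.t1 0.8167 697.742 0.5722
    5 G00010 G00010.t2 G00010.t1 0.7500 472.233 0.4523
```

Ten switch genes were planted; 9 pairs clear the permutation thresholds
(S1 > 0.60 **and** IG > 0.31) and 8 also pass the three switch filters. The
top pair reverses in ~98% of samples (S1 = 0.967) and its rule alone carries
0.85 bits about the class. Cross-validation picks a 3-rule majority-vote
model (k_opt = 3, mean held-out accuracy 1.0), and a blind test on the 10
unpaired tumor samples labels all of them correctly:

```python
unpaired = [s for s in dataset.sample_ids if s.startswith("U")]
frac, votes = res.blind_test(dataset.abundance[unpaired], "tumor")
# frac == 1.0
```

The same workflow is available from the shell:

```sh
isopair simulate --out data --seed 42
isopair score    --expression data/expression.tsv --labels data/labels.tsv --out ranking.tsv
isopair pipeline --config run.yaml --seed 0 --out results/
```

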