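# Methods

## Model

The package treats differential splicing between two sample classes as a
problem of *order reversal*: a splicing change is a pair of isoforms of one
gene whose relative expression ranking flips between classes. For isoforms
*i*, *j* of gene *g* with per-sample expression *x_i*, *x_j* (TPM) and
classes C1 (reference/"normal") and C2 ("tumor"):

    S1(i, j) = P(x_i > x_j | C1) + P(x_i < x_j | C2) − 1  ∈ [−1, 1]

estimated by within-class frequencies. S1 is a probability-scale measure of
reversal consistency; it uses only within-sample order, so it is invariant
under any strictly monotone per-sample transform of expression, which is why
no between-sample normalisation is applied anywhere.

**Tie policy.** RNA-seq transcript estimates contain many exact ties, above
all double zeros. The default ("strict") policy counts a tied sample in the
denominator of both frequencies but in neither numerator: a pair tied
everywhere scores S1 = −1, and partially-unexpressed pairs are penalised in
proportion to how often they are tied. The alternative "half" policy credits
each tie 0.5 to both orders (so an all-tie pair scores 0). Strict is the
default because it cannot promote unexpressed pairs into the ranking; both
policies are exposed on every entry point (`tie_policy=`, `--tie-policy`).

**Orientation.** For each unordered pair the orientation maximising S1 is
kept. In the maximising argument order (i, j), isoform *i* sits above *j* in
C1, so *i* is the *normal isoform* and *j* the *tumor isoform*; rules are
reported as (tumor_isoform, normal_isoform) with semantics
"tumor_isoform < normal_isoform ⇒ C1, else ⇒ C2". The "else" branch means
an exactly tied sample (e.g. both isoforms zero) votes C2; this literal
reading is configurable (`tie_vote`). On an exact S1 tie between the two
orientations, the dataset's transcript order decides, deterministically.

**S2 tie-break.** Within each sample, all transcripts are ranked (rank 1 =
lowest expression; average ranks on ties). S2 is the absolute difference
between the class means of the within-sample rank difference r_i − r_j. It
orders pairs with equal S1 by the *magnitude* of the rank shift. S2 is
direction-invariant by construction (outer absolute value).

**Listing.** Only same-gene pairs are scored; each gene contributes its best
pair by (S1, then S2) — deterministic remaining ties broken by pair
enumeration order — and the global ranking sorts by S1 desc, S2 desc, gene
id asc. All-tie (degenerate) pairs are excluded, as are genes whose best
orientation still has S1 < 0: a negative best score means ties dominate and
the pair cannot be positive evidence of a reversal.

**Information gain.** Each listed rule's vote partitions the training
samples; IG = H(class) − Σ_v p(v) H(class | vote = v), in bits, with
0·log 0 = 0. IG is 0 for a constant vote and H(class) (1 bit when balanced)
for a perfect rule.

## Model selection and classification

Classifiers are odd-length ordered rule lists combined by simple majority
vote (odd k ⇒ no vote ties). Cross-validation leaves out one patient's
tumor+normal pair per fold (the held-out unit is the patient, keeping folds
balanced), recomputes the entire ranking on the remaining samples, and
evaluates the top-k classifiers for k = 1, 3, …, k_max on the two held-out
samples. k_opt is the smallest odd k attaining the maximal mean accuracy;
means are rounded to 1e-10 before comparison so float noise cannot inflate
k_opt. The final model takes the top k_opt pairs of the full-data ranking.
A fold whose ranking lists fewer than k pairs is evaluated at the largest
available odd k rather than failing; `build_final_model` still errors in
that situation because a published model must exist as specified.
k_max defaults to 11: selected models are intentionally small, and accuracy
plateaus well below that in practice.

Accuracy is (TP+TN)/(TP+TN+FP+FN), symmetric under swapping the
positive-class designation (property-tested). Blind tests report the
fraction of held-out samples labelled correctly plus the histogram of
per-sample vote counts for the expected class.

## Significance

The null is a max-statistic label permutation: n_perm (default 1000)
uniform shuffles of the class labels (class sizes preserved, pairing
ignored), recomputing the ranking each time and recording the top S1 and
the top IG over the per-gene best pairs. A pair is significant iff its S1
AND its IG strictly exceed the respective maxima — family-wise error
control at roughly the 1/(n_perm+1) scale. Empirical p-values
(1 + #{perm ≥ obs})/(n_perm + 1) are reported alongside for transparency.
Only the ranking is recomputed per permutation; rerunning the full CV per
permutation (available as `permute_with_cv`) cannot change the thresholds
because CV accuracy does not enter the significance criterion. A single
seeded generator draws permutations sequentially, making the null
prefix-stable in n_perm. The fully degenerate case (every pair tied in
every sample) is reported explicitly (`all_degenerate`) instead of emitting
misleading thresholds.

The subtype mode draws, n_iter times (default 100), a balanced subsample
(default 45 target-subtype samples vs a pool of 15 from each other subtype),
reruns ranking + permutation test on the subsample, and reports the fraction
of iterations in which each pair was significant; pairs above the frequency
cutoff (default 0.8) form the subtype model, truncated to an odd count.

## Switch detection

From the significant pairs, switches must satisfy all of: S1 > 0.5 (the
reversal holds in more than 75% of samples), Spearman rho < −0.8 between the
two isoforms' PSI vectors, and mean TPM > 1 for each isoform in at least one
class (possibly different classes). PSI is TPM divided by the gene's total
TPM; samples where the gene is silent get missing PSI (never 0) and are
dropped pairwise from the correlation, with ≥3 complete observations
required. The correlation is computed on PSI rather than TPM, jointly across
the paired tumor and normal samples: a genuine dominant-isoform swap places
the two classes at opposite ends of both PSI ranges, which is what drives
rho strongly negative, and for a two-isoform gene PSIs are exactly
complementary so rho = −1 wherever both vary. Protein impact is classified
from supplied per-transcript CDS sequences into: no CDS / no normal CDS /
no tumor CDS / no protein affected (identical CDS, UTR-only change) /
protein affected.

## Mutation association

The universe is the tumor samples with both expression and mutation data
(an explicit DNA-profiled set can be supplied; otherwise all tumor samples
are assumed profiled). S = samples fulfilling the switch's tumor rule,
M = samples with ≥1 mutation overlapping the switch region — the union of
the two transcripts' genomic spans (scope "transcript") or the single
gene-wide interval (scope "gene"), closed 1-based intervals, optionally
restricted to protein-affecting mutation classes. Statistics: Jaccard
J = |M∩S|/|M∪S| (0, flagged, on an empty union); plug-in mutual information
of the two indicators in bits; mutual exclusion mx = 2·min(n10, n01)/N.
Each statistic gets a z-score against the n_background = 100 genes nearest
in |median isoform length difference| (genes with ≥2 isoforms; ties by gene
id; same S, each background gene's own M). The nearest-neighbour background
is fully deterministic. A constant background yields a missing, flagged
z-score. ΔPSI = PSI(tumor isoform) − PSI(normal isoform) per tumor sample is
compared between mutated and non-mutated samples by a two-sided
Mann–Whitney test (exact for small untied groups, tie-corrected normal
approximation otherwise; all-tied data returns p = 1); a per-patient paired
variant (tumor minus matched normal ΔPSI) is available behind a flag.
Benjamini–Hochberg adjustment is applied across all tested switches at
α = 0.05, with raw p-values always emitted.

## Synthetic data generator

The generator emulates the statistical structure the method assumes, not any
particular sequencing artefact. Defaults (the package's study conditions):
1000 genes with 2–5 isoforms, 30 patient pairs plus 30 unpaired tumors, 50
switch genes, penetrance 0.95. Gene abundance is log-normal around 100 TPM
(σ = 1). For a switch gene the dominant isoform takes a U(0.6, 0.85) share
and the designated partner U(0.15, 0.4) of the dominant's share — a
dominant-to-minor ratio of ~2.5–6.7×, a realistic margin for a clearly
dominant isoform — with any remaining isoforms kept below the partner so the
planted pair are the gene's two most abundant. In each tumor sample,
independently with probability = penetrance, the two designated isoforms'
mean abundances are *swapped*: gene-level expression is untouched, so
planted signal is purely a splicing change and gene-level models gain
nothing from it. Multiplicative log-normal noise (σ = 0.5) and Bernoulli
zero-inflation (5%) are then applied and each sample renormalised to 1e6 —
this produces exactly the tied, non-strictly-monotone rankings the strict
tie policy exists for. Optional layers: tumor subtypes with
subtype-restricted switches (to exercise the subsampling mode) and a
two-rate mutation model (P(mut|switch sample) vs P(mut|non-switch sample)
on planted genes, a background rate elsewhere), with mutations placed
uniformly in the gene span. Transcript structures are laid along one
chromosome with two exons per transcript and offset spans, so
transcript-scope and gene-scope mutation overlap genuinely differ.
Everything is a deterministic function of the seed, and a truth table
records planted pairs, per-sample switch realisations and mutation flags.

What the generator does *not* emulate: library-size and GC biases, batch
effects, patient-specific baselines, correlated genes, realistic exon
structure. Passing tests therefore demonstrate the statistical machinery —
ranking, calibration, recovery — under the model's own assumptions, not
performance on any real cohort.

## Numerical and design choices

- **Vectorised scoring.** Per-sample order comparisons between pair members
  are label-independent and precomputed once; scoring a labelling
  (CV fold, permutation, subsample) is a handful of matrix–vector products.
  This is what makes 1000-permutation nulls and leave-one-pair-out CV cheap.
- **Determinism.** All tie-breaks (orientation, per-gene best, global sort,
  background-gene selection) are total and documented; every stochastic
  stage takes a seed and is byte-reproducible; permutation streams are
  prefix-stable in n_perm.
- **Degenerate inputs.** Zero-count samples → zero TPM column with a
  warning; silent genes → missing PSI; all-tie pairs → excluded and
  flagged; constant z-score backgrounds → missing with a flag; empty ΔPSI
  groups → missing p-value with a flag.
- **Test calibration.** Two statistical subtleties surfaced during
  verification and are reflected in the tests: (1) CV fold
  accuracies within one dataset share the selected rule and are strongly
  correlated, so chance-level calibration is asserted across independent
  replicate datasets using the empirical standard error (3σ) rather than a
  per-replicate binomial band; (2) two-sided Mann–Whitney p-values are
  discrete and slightly conservative at the group sizes used, so null
  calibration is asserted as absence of anti-conservatism (one-sided KS)
  plus a correct 5% rejection level rather than exact uniformity.
- **Problem sizes.** The test suite and `scripts/acceptance.py` use
  desk-scale simulations (hundreds to 1000 genes, tens of patient pairs,
  100–200 permutations, 15–20 replicates per calibration), chosen so the
  full verification cycle completes in well under a minute while every
  statistical property remains comfortably measurable.

## Known limitations

- S2 and IG follow the classic top-scoring-pairs literature definitions
  (average rank difference; vote-partition entropy); other variants exist.
- The permutation null ignores patient pairing; with strong patient effects
  the null is slightly conservative.
- Gene-level mode scores all cross-gene pairs (quadratic); it is intended
  for comparisons on modest gene sets, not transcriptome-wide runs.
- PSI anti-correlation uses paired samples only; unpaired tumors contribute
  to scoring and blind tests but not to the switch correlation filter.
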