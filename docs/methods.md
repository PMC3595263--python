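# Methods

This note documents the models, conventions and numerical choices behind
`mirpair`, and what the synthetic cohorts do and do not establish about real
data.

## Relative quantification

Ct values are log2-scale by construction (one cycle = one doubling). The
package uses the ΔCt method throughout: ΔCt(m, s) = Ct(m, s) − Ct(ref, s),
relative expression 2^(−ΔCt), and per-patient log2 fold change
ΔCt(primary) − ΔCt(metastatic), so positive values mean higher expression at
the metastatic site. Fold changes are stored in log2 with the linear value
derived as 2^log2FC at the point of use, so the two scales cannot drift.

Conventions the instrument literature leaves open, with our defaults:

- **Detection threshold** — 35 cycles, configurable (`call_detection`). A
  well is detected iff it carries a value and Ct < threshold; an assay
  amplifying only around Ct ≈ 36 is therefore *not* detected at the default.
- **Undetected wells** — carried as an explicit status flag, never as a
  sentinel value, so censoring policy stays a downstream choice.
  `censor_undetected` assigns undetected wells the maximum cycle tested
  (40, configurable) and flags them censored; the flag propagates through
  ΔCt and fold changes. The differential screen does *not* censor by
  default: undetected wells are missing data there, and censoring is used
  to bound a fold change for an assay absent in one condition.
- **Replicate reference wells** — combined by the arithmetic mean of the
  reference Ct per sample.
- **Efficiency correction** — out of scope; the ΔCt method assumes 100%
  amplification efficiency.

## Differential screen

miRNAs detected in at least `min_detected` samples (default 2, counted over
all samples of both sites) are tested with a paired t-test,
t = d̄/(s_d/√n) with sample sd (n−1 denominator) and a two-sided p from the
Student t distribution with n−1 df, computed via `scipy.stats.ttest_1samp`
on the per-patient differences. The test operates on the log2 fold-change
scale (the ΔΔCt scale), which is the additive, approximately normal scale
for qPCR data; a `test_scale="linear"` option tests the linear fold changes
against 1 instead. Patients with a missing side are dropped per miRNA and
`n_pairs` records the count used; fewer than 2 complete pairs is an error.
Zero-variance difference vectors are flagged degenerate rather than
producing silent infinities: all-zero differences give t = 0, p = 1 by
convention; constant nonzero differences give p = 0 (the limiting value)
with t = ±inf and the flag set.

Selection keeps rows with p < alpha (default 0.05), deliberately
uncorrected — this is a discovery screen — while a Benjamini–Hochberg
column (`p_bh`, via `scipy.stats.false_discovery_control`) is emitted for
users who want it. Fold-change summaries report mean ± s.e.m. (sd/√n) of
the per-patient *linear* fold changes, the form usually plotted.

## Clustering

`pearson_distance` computes d = 1 − r between rows; missing cells are
handled pairwise-complete with a minimum overlap of 3 shared features
(error otherwise), and zero-variance rows are rejected by name. `upgma`
implements textbook unweighted average linkage: merge heights are the
unweighted mean of all cross-pair *leaf* distances, maintained with the
exact Lance–Williams update d(a∪b, k) = (n_a d(a,k) + n_b d(b,k))/(n_a+n_b).
"Average linkage" is ambiguous between UPGMA and WPGMA in some tools; the
unweighted definition is used here and verified in tests against an
exhaustive reference that recomputes every average from the original leaf
matrix. Ties in the minimum distance are broken by the lexicographically
smallest member id, so item order never changes merge heights (only
labels). Trees are ultrametric; Newick export places each leaf at depth
height/2 under its merge, and `cut(k)` undoes the top k−1 merges, labelling
each cluster by its smallest member id. The pipeline clusters the selected
miRNAs' log2 fold changes (complete cases over miRNAs so every patient
keeps a full profile); linear fold changes can be clustered by transforming
the table first.

## Target anti-correlation permutation test

Preparation: `quantile_normalize` maps every sample onto the across-sample
mean of sorted values (ties get the average of the quantile values they
span, via average ranks and linear interpolation — so the sorted columns of
the output are exactly identical). `lowest_quartile_filter` removes genes
whose value is below the per-sample 25th percentile in *every* sample;
genes low in only some samples are kept.

The miRNA enters as −ΔCt (log2 relative expression) per sample; correlation
is computed across all samples pooled (primary + metastatic, 18 in the
default design), which maximizes the expression contrast a differential
miRNA provides. Per-gene Pearson r against the miRNA vector uses the
centered dot-product formula, vectorized over genes.

The observed statistic is the mean r over the predicted target set — the
union across prediction sources — intersected with the filtered matrix
(missing targets are counted and excluded; the null set size matches the
post-intersection count). The null draws `n_perm` (default 1,000) sets of
that size without replacement from the non-target genes; the pool is sorted
by gene id before drawing so the null is invariant to input row order.
Both one-sided p-values are reported with the add-one (permutation-exact)
correction p = (1 + #{null ⋚ observed})/(N+1), so p ∈ [1/(N+1), 1] and is
never zero; `p_low` (the repression direction) is primary. Randomness comes
from one named `numpy` generator seeded per test; identical seeds reproduce
the null exactly.

`anticorrelated_gene_list` applies a strict r < threshold rule (default
−0.3, r = −0.3 itself excluded) and returns genes most-negative first; it
feeds downstream enrichment tools and is not itself a significance test.

## Synthetic cohorts

The generator emulates a paired two-site study: `n_patients` = 9 patients ×
2 sites, `n_mirnas` = 377 assays plus `n_reference_wells` U6 snRNA wells,
and a matched mRNA matrix over `n_genes` = 2,000 genes. The generative
model is

    Ct(m, s) = Ct_ref(s) + baseline_ΔCt(m) − log2FC(m)·[s metastatic] + ε,
    ε ~ N(0, pair_noise_sd²)

with noise additive Gaussian on the Ct scale (log-normal measurement error
on the linear scale, the usual qPCR approximation). Reference wells are
noise-free by default (`reference_noise_sd = 0`) so ΔCt noise is
attributable to the miRNA well. Wells whose latent Ct exceeds
`dropout_ct_cutoff` (35) are undetected. Key defaults and why:

- `baseline_dct_mean = 16`, `baseline_dct_sd = 4`, `reference_ct_mean = 20`:
  with the 35-cycle dropout this yields ≈ 180–200 of 377 assays expressed
  in ≥ 2 samples, matching the roughly-half detection rate typical of tumor
  array cards.
- `pair_noise_sd = 0.5` cycles: no measurement-error magnitude is published
  for these cards; half a cycle per well is a conventional, realistic
  choice and is documented as such, not a measured value.
- 17 planted miRNAs with |log2FC| ∈ [1.5, 3.2], three down-regulated,
  mirroring a screen dominated by up-regulation with a small down cluster.
  Planted miRNAs draw baselines from U(5, 10) so they sit safely inside the
  detected range — a planted effect on an undetectable assay would be
  unrecoverable by construction.
- Target sets: per planted miRNA, two sources of exactly `targets_per_mirna`
  (50) genes sharing a `source_overlap` (0.6) fraction, disjoint across
  miRNAs; the union (70 genes at defaults) is the truth set. mRNA model:
  gene baseline N(7, 2) (log2 array-signal scale) + `repression_slope`
  (−0.5) × the miRNA's −ΔCt for target genes + N(0, `mrna_noise_sd` = 0.5).

Everything is deterministic given `SimParams` (including the seed): the
cohort, target sets and mRNA matrix use independently spawned streams of
one generator, so regenerating any piece is byte-identical.

**What the synthetic cohorts do not emulate:** stromal admixture,
plate/batch effects, amplification-efficiency differences, pre-amplification
bias, correlated gene–gene expression structure, and miRNAs targeting
overlapping gene sets. Passing tests demonstrate that the estimators and
tests are correct and calibrated under the stated generative model, not
that a particular biological cohort will show these effect sizes.

## Pipeline and reproducibility

`run_pipeline` executes the enabled stages in order, resolving dependencies
in memory first, then from configured input paths, and fails with an error
naming the stage otherwise. Every run writes a resolved-configuration YAML,
a parameter manifest, and a JSON report carrying the seed, a SHA-256 hash
of the analysis parameters (the output directory is excluded from the hash),
and stage-by-stage counts matching the structured log lines. Identical
configuration + seed reproduces every artifact byte for byte. Permutation
seeds for the target stage are derived deterministically from the run seed
and the miRNA's position.

Problem sizes in the test suite and acceptance script (oracle checks at
n ≤ 12 vectors and n ≤ 7 trees; 50–500 replicate cohorts; 199–1,000
permutations) were chosen so the full statistical checks — calibration,
recall, oracle equivalence — run comfortably on a laptop while keeping
Monte-Carlo error well below the tested tolerances.

## Known limitations

- The paired t-test assumes approximately normal log2 fold changes; no
  nonparametric alternative is provided.
- Pairwise-complete Pearson distances can yield non-metric matrices; UPGMA
  does not require metricity, but heights then lack the usual guarantees.
- The permutation null treats genes as exchangeable; correlated gene
  modules in real data make it anti-conservative, which is one reason the
  add-one correction and both tails are reported.
- Censored (Ct = 40) values bound, rather than estimate, expression; fold
  changes involving them are flagged and should be read as limits.
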