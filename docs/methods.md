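# Methods

This note documents the models and procedural rules implemented in
`nfypipe`, the defaults chosen where a rule left room, what the synthetic
cohort generator does and does not emulate, and the numerical conventions
used throughout.

## Statistical primitives (`stats_core`)

**Wilcoxon rank-sum / Mann–Whitney U.**  The statistic is
U = R₁ − n₁(n₁+1)/2 with midranks for ties.  For tie-free data with pooled
n ≤ 12 the p-value is exact, from full enumeration of all C(n, n₁) rank
assignments; otherwise a normal approximation is used with the
tie-corrected variance n₁n₂/12 · [(n+1) − Σ(t³−t)/(n(n−1))] and a 0.5
continuity correction.  Two-sided p = min(1, 2·min(one-sided)); this is the
convention everywhere in the package.  Samples in which every pooled value
is identical carry no information and return p = 1 with a degenerate flag.

**Jonckheere–Terpstra.**  For ordered groups,
J = Σ_{i<j} #{(a,b) : a ∈ group_i, b ∈ group_j, a < b} + ½·#ties.  When the
multinomial number of group assignments is ≤ 200 000 the p-value is exact
by enumeration (which also handles ties correctly, since assignments of
tied values are enumerated with their multiplicity); otherwise the normal
approximation with E[J] = (N² − Σn_k²)/4 and the standard tie-free variance
[N²(2N+3) − Σn_k²(2n_k+3)]/72 is used, again with a 0.5 continuity
correction.  The ½-count for ties is the standard convention; no additional
tie correction of the variance is applied, because the tied cases that
matter at small n are covered by exact enumeration and the pipeline applies
the test to continuous markers.

**Benjamini–Hochberg.**  Step-up q-values
q_(i) = min_{j≥i} (m·p_(j)/j), clipped at 1, returned in input order.

Calibration of all three tests (empirical type-I error within
[0.035, 0.065] at α = 0.05 over 2000 null replicates) is checked by the
acceptance suite, with the trend test exercised exactly as the pipeline
uses it: markers drawn independently of rank bins built from a separate
ratio variable.

## Subtype classification

Signature genes are median-centered in log2(TPM+1) space across *all*
samples (the transform is recorded on the matrix and applied lazily, so it
can never be applied twice).  Centroids are per-subtype means of centered
expression over labelled training samples — the simplest estimator
consistent with a "predictor centroid"; a precomputed centroid matrix can
be supplied instead, so both the rebuild-from-labels and external-centroid
paths are supported.  Classification computes the Pearson correlation of
each sample with each centroid over the shared genes and assigns the
argmax.  Conventions: exact ties are broken by centroid column order and
flagged; a sample with zero variance over the shared genes, or with fewer
than 50% of the signature genes available, is `unassigned`.  Log2(TPM+1)
was chosen as the correlation space; since Pearson correlation is invariant
to per-sample affine maps, the choice affects only the gene weighting, not
the invariances tested.

## Differential expression

Per-gene comparisons use the rank-sum test on linear TPM with BH adjustment
across all tested genes; the fold change is log2((mean_a + c)/(mean_b + c))
of group means with pseudocount c = 0.5 TPM.  The DEG rule is strict:
q < 0.01 and |log2FC| > 2.  Genes with zero variance across both groups are
excluded from testing and reported as `ns` with p = q = 1.  A
negative-binomial GLM engine (DESeq2-style dispersion modelling and
shrinkage) is intentionally not reproduced: the package's contribution is
the threshold/filter logic and the downstream pipeline, and the
distribution-free test keeps the stage self-contained.  Note that the raw
mean fold change at a planted log2 effect of exactly 2 sits *at* the
threshold (the pseudocount pulls it slightly below), so the strict filter
admits few genes at that effect size; spike-in recovery is therefore
assessed at effect 3.

## Isoform ratios, binning, trends

The ratio is (long + ε)/(short + ε) with ε = 0.01 TPM, keeping zero
denominators finite while leaving typical values (tens of TPM) essentially
untouched.  Rank binning splits n samples into k contiguous groups, sizes
as equal as possible with the larger bins at the low-ratio end
(n = 23, k = 10 → 3,3,3,2,…,2), ties broken by stable input order: the
partition is a deterministic, monotone-invariant function of the values.
Trend tests feed the bin-ordered marker groups to Jonckheere–Terpstra;
per-bin subtype composition tables normalise each bin's subtype counts to
fractions.

## Deconvolution

Mixing of cell populations is linear in transcript abundance, so solving
happens on linear TPM.  The basis is the per-type mean profile of a
labelled single-cell matrix; per-sample proportions are NNLS coefficients
normalised to the simplex.  Gene selection defaults to the union of
per-type marker sets (or, absent markers, the top basis-fold genes per
type); `all` and `top_variance_k` are available.  An optional one-step
variance-reweighted NNLS refinement down-weights high-signal genes.
Ensemble/tree-guided reference weighting used by some deconvolution tools
is out of scope — the analysis uses a single reference, and plain NNLS is
the verifiable core of that family; its stated accuracy surface is
parameter recovery on synthetic mixtures (exact on noiseless mixtures, mean
per-sample RMSE < 0.05 on negative binomial mixtures at depth 10⁶), not
concordance with any particular R package.  The fibroblast filter retains
samples with predicted fibroblast proportion strictly below 0.30.

## Signature scoring

Z-scores are computed per gene over the *relevant sample subset* — the
subset is chosen first, then standardised (CAF signatures within
Mesenchymal-classified tumors; the p-EMT signature on fibroblast-filtered
samples).  The alternative order (standardise globally, then restrict) is
deliberately not used, and a test pins the implemented order.  The score is
the per-sample median Z over the signature's genes present in the matrix;
missing genes are logged, an entirely absent signature is an error.
Partitioning uses the floor rule: top ⌊0.4n⌋ High, bottom ⌊0.4n⌋ Low, the
remainder discarded, ties by stable order.  log2(TPM+1) (pseudocount 1) is
used because TPM matrices contain zeros.

## Survival

Kaplan–Meier estimation and the two-group log-rank test are delegated to
`lifelines` behind this module's interface; deaths are processed before
censorings tied at the same time (the standard product-limit convention).
The quartile rule labels the bottom ⌊0.75n⌋ samples Low and the rest High,
ties by stable order; two-gene stratification is the cross product of two
independent quartile rankings (four groups), compared pairwise with BH
correction.  The progression-free interval is the sole endpoint; no Cox
modelling or covariate adjustment is performed.

## Mutation and HPV associations

"Frequent" mutations are genes carried by strictly more than 80 tumors
(the strict inequality is part of the rule).  Each comparison is an
unpaired rank-sum test of carriers versus non-carriers — the groups are
independent samples, so the unpaired test is the appropriate choice — with
direction the sign of the median difference and star annotation
(* p<0.05, ** p<0.01, *** p<0.001).  HPV comparisons exclude
unknown-status samples.  Raw p-values are reported by default (matching
the starred-boxplot style of presentation); BH adjustment is a flag.

## Synthetic cohort generator

The generator is the package's study-condition definition, not a test
fixture: its defaults are chosen once to mirror the cohort the analyses
were designed for, and all planted structure is returned as ground truth.

* **Scale**: 522 tumors and 44 normals by default; tests and the
  acceptance script use smaller cohorts (stated with each result) purely to
  keep simulation sizes proportionate.
* **Expression**: negative binomial counts (Var = μ + 0.2μ²) around a
  lognormal baseline, library-normalised to TPM.  Subtype signature blocks
  (50 genes each) are elevated 2^2-fold in their subtype's tumors; NF-YA,
  NF-YB and NF-YC are elevated 2.0/1.6/1.2-fold in tumors, mirroring the
  strong/moderate/slight subunit overexpression the pipeline is meant to
  detect.
* **Isoforms**: per-tumor log2 ratio ~ Normal(log2 m_s, 0.5) with subtype
  means m_s = 1.5 (Mesenchymal), 0.6 (Basal, Classical), 0.3 (Atypical),
  0.4 in normals; TP53 carriers shift the ratio +0.585 log2 (×1.5);
  HPV-positive tumors shift the short isoform up (+0.4 log2) and the long
  isoform down (−0.3 log2).
* **p-EMT coupling**: a 30-gene block whose expression scales as
  2^(0.75·z) in the standardised per-tumor log-ratio z, so ratio bins show
  a real monotone trend for this block and none for independent genes.
* **HPV and mutations**: independent Bernoulli draws per subtype/gene
  (HPV positivity 0.50 in Atypical versus ~0.1 elsewhere; mutation rates
  0.12–0.65 across twelve recurrently mutated genes, TP53 highest).
* **Cell mixtures**: a 3-type reference (Cancer/Fibroblast/Immune, 40
  markers each at 2³-fold) with per-tumor Dirichlet proportions,
  fibroblast-heavy in Mesenchymal tumors (α = (4, 4.5, 1.5) versus
  (8, 1–1.5, 2–2.5)); bulk mixture profiles are NB-resampled at depth 10⁶.
  The mixture matrix is a companion to the gene matrix rather than its
  source, which keeps the subtype structure and the compositional structure
  independently testable.
* **Survival**: exponential event times with hazard 1/2400 per day for
  tumors in the top quartile of short-isoform TPM and 1/1000 otherwise
  (high NF-YAs protective), independent exponential censoring at rate
  1/1500.  Censoring independent of group keeps log-rank calibration
  analyzable.

What the generator does **not** emulate: transcript-length effects in TPM,
correlated gene–gene noise, isoform quantification uncertainty,
subtype-dependent censoring, batch effects, or any coupling between the
mutation flags and gene-level expression (only the isoform ratio responds
to TP53).  Passing tests therefore demonstrate correctness of the
procedures under the stated generative assumptions, not robustness to the
full messiness of real RNA-seq cohorts.

Null configurations (zero effect sizes) plant no structure and are used to
calibrate every downstream test.  All randomness flows from a single seed
through `numpy.random.default_rng`; reruns are bit-identical.

## Numerical conventions and edge cases

Tab-separated text is the canonical on-disk format; floats are written with
`%.10g` so rerun outputs are byte-identical.  Missing annotation fields use
the sentinel `NA`.  TPM matrices are stored linear with the log2 transform
recorded in a flag (prevents silent double-logging).  Degenerate inputs are
handled explicitly rather than erroring where a defined answer exists:
constant test inputs give p = 1 with a flag, zero-variance classification
profiles give `unassigned`, an all-zero NNLS solution yields uniform
proportions with the sample flagged, constant genes give zero z-score rows,
and partitions of fewer than 5 samples warn but proceed.  Cohorts smaller
than 4 tumors skip the quartile-based survival grouping.

## Known limitations

The rank-sum DE stage has different power and fold-change behaviour from
count-model engines, so printed DEG counts from any real cohort are not
expected to be reproduced.  The classifier's centroid construction is the
mean-of-centered-profiles estimator; other published centroid variants
(shrunken centroids, correlation-weighted means) would classify borderline
samples differently.  Deconvolution accuracy depends on marker separation
in the reference; with closely related cell types NNLS proportions are
biased toward the dominant type.  The log-rank test is asymptotic; for
very small strata an exact test would be preferable.
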