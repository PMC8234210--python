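# nfypipe

Transcriptomic analysis pipeline for NF-Y subunit and splice-isoform
expression in head-and-neck squamous cell carcinoma (HNSCC) style cohorts.

NF-Y is the trimeric CCAAT-box-binding transcription factor (subunits NF-YA,
NF-YB, NF-YC).  NF-YA occurs as two splice isoforms — "long" (NF-YAl, exon 3
included) and "short" (NF-YAs) — and the per-sample TPM ratio
NF-YAl/NF-YAs is the central statistic of this pipeline: it differs between
molecular subtypes, tracks partial epithelial-to-mesenchymal-transition
(p-EMT) and cancer-associated-fibroblast (CAF) programs, and stratifies
progression-free survival.

The package is a toolkit for the complete multi-stage analysis:

1. **Molecular subtyping** — nearest-centroid classification into the four
   HNSCC expression subtypes (Atypical, Basal, Classical, Mesenchymal):
   signature genes are median-centered in log2(TPM+1) space across all
   samples and each tumor is assigned the subtype whose predictor centroid
   attains the largest Pearson correlation *r*.
2. **Differential expression** — per-gene Wilcoxon rank-sum tests with
   Benjamini–Hochberg adjustment; a gene is a DEG when FDR < 0.01 and
   |log2 FC| > 2.
3. **Isoform-ratio trend analysis** — samples ranked by
   (NF-YAl + ε)/(NF-YAs + ε), split into 10 equal-size bins, and marker
   trends across bins tested with the Jonckheere–Terpstra statistic
   J = Σ_{i<j} #{a ∈ bin_i, b ∈ bin_j : a < b} (ties count ½).
4. **Deconvolution** — per-sample cell-type proportions by non-negative
   least squares against a labelled single-cell reference basis, with
   removal of samples at ≥ 30% predicted fibroblast content.
5. **Signature scoring** — per-sample median Z of log2(TPM+1) over a gene
   signature, then a High (top 40%) / Low (bottom 40%) split with the middle
   20% discarded.
6. **Mutation / HPV associations** — rank-sum comparisons of subunit and
   isoform levels between carriers of each frequent mutation (> 80 carriers)
   and the rest, and between HPV-positive and HPV-negative tumors.
7. **Survival** — Kaplan–Meier product-limit curves of the progression-free
   interval with two-group log-rank tests; expression stratification uses
   the quartile rule (Low = bottom three quartiles, High = top quartile) and
   two-gene stratification joins two independent quartile rankings.

The rank-sum, Jonckheere–Terpstra and Benjamini–Hochberg primitives are
implemented in `nfypipe.stats_core` (exact enumeration for small instances,
tie-corrected normal approximations otherwise); Kaplan–Meier and log-rank
computations are delegated to `lifelines`; NNLS uses `scipy.optimize.nnls`.

A first-class synthetic cohort generator (`nfypipe.synthetic_data`)
reproduces the statistical structure these analyses assume — negative
binomial counts scaled to TPM, subtype signature blocks, subtype-dependent
isoform ratios, HPV concentrated in the Atypical subtype, mutation flags,
known cell-type mixtures, and censored exponential survival — and returns
all planted structure as ground truth, so every stage is testable without
any data download.

## Worked example

```python
from nfypipe.pipeline import PipelineConfig, run_pipeline
from nfypipe.synthetic_data import CohortConfig

config = PipelineConfig(
    cohort=CohortConfig(n_tumor=200, n_normal=30, n_genes=1000),
    seed=1, output_dir="demo_out")
results = run_pipeline(config)

calls = results["classify"]
truth = results["cohort"].truth["subtype_labels"]
print(f"subtype recovery: {(calls['subtype'] == truth.loc[calls.index]).mean():.3f}")
print(results["isoform_trend"]["trend_tests"].round(4))
comp = results["isoform_trend"]["bin_composition"]
print("Mesenchymal fraction, bins 1/10: "
      f"{comp.loc[1, 'Mesenchymal']:.2f} / {comp.loc[10, 'Mesenchymal']:.2f}")
print(results["survival"]["tests"].loc[["NFYAs", "NFYAl"]].round(4))
```

prints

```
subtype recovery: 1.000
                 J  p_value         method
marker
NFYB        8546.0   0.8329  normal_approx
NFYC        8569.0   0.8204  normal_approx
pEMT_mean  17026.0   0.0000  normal_approx
Mesenchymal fraction, bins 1/10: 0.00 / 1.00
             comparison  statistic  p_value
stratifier
NFYAs       High vs Low    18.7760    0.000
NFYAl       High vs Low     6.4674    0.011
```

Reading the numbers: every tumor receives its true subtype (the planted
log2 signature effect of 2 is easily separable by centroid correlation);
the p-EMT program, which the generator couples to the isoform ratio, shows
a maximal Jonckheere trend across the ten ratio bins (p ≈ 0) while NF-YB and
NF-YC, generated independently of the ratio, do not; the top ratio bin is
pure Mesenchymal, the bottom bin contains none; and the planted protective
effect of high NF-YAs yields a strongly significant log-rank split
(χ² = 18.8), while the NF-YAl split is an indirect, weaker association.
Each stage also writes its table under `demo_out/`, together with a
`run_log.yaml` carrying the seed and a config hash; reruns with the same
seed are byte-identical.

The same stages are available as shell subcommands
(`nfypipe simulate | classify | de | isoform | deconv | signature | assoc |
survival | run`), reading and writing tab-separated files.

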