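# imputeval

Assessing genotype-imputation accuracy from low-pass sequencing, and
what imputation errors cost a case-control GWAS.

Low-pass (~1x) whole-genome sequencing plus imputation against a
reference haplotype panel is a cheap alternative to genotyping arrays,
but the imputed genotypes carry frequency-dependent errors —
heterozygotes at rare alleles are the most fragile. `imputeval` is a
library for researchers who have (or simulate) a paired dataset of
imputed genotypes and a high-coverage truth set. It answers three
questions:

1. **How accurate is the imputation?** Three-way variant-site overlap
   between imputed, truth and panel call sets; 3x3 truth-by-imputed
   confusion tables stratified by 0.01-wide minor-allele-frequency
   (MAF) bins; concordance, non-reference concordance, dosage r², and
   the imputation quality score
   `IQS = (P_o - P_c) / (1 - P_c)` — chance-corrected agreement
   (Cohen's-kappa form) that is robust to the inflated raw concordance
   of rare variants.
2. **How should I filter?** Dual-threshold confidence filtering: a
   genotype call is low-confidence when its maximum genotype
   probability (GP) is below X; a site is removed when it holds >= Y
   such calls. Strategies are scored over a (X, Y) grid by
   TPR/FPR/FDR/keep-rate against the truth, tracing ROC curves.
3. **How many samples does my study need?** Errors are summarized as
   row-stochastic 3x3 channels P per MAF bin (`I = G·P` maps true
   genotype counts to expected imputed counts). Case-control power
   for the 2x2 chi-square test on minor-allele carrier status uses
   Cohen's `w = sqrt(Σ (p_alt - p_null)² / p_null)` and the noncentral
   chi-square with ncp = N·w² (alpha = 5e-8, target power 0.8),
   yielding required sample sizes and the *extra* samples an imputed
   study needs over one with true genotypes.

A seeded synthetic-data generator (`SimConfig`, `generate_truth`,
`generate_imputed`, `generate_overlap_trio`) produces cohorts with the
assumed error structure — HWE genotypes, MAF-decaying channels with
elevated heterozygote error, GP triplets calibrated to correctness —
so the whole pipeline runs and is tested without any external data.
See `docs/methods.md` for the model, defaults, and limitations.

## Worked example

```python
import imputeval as iv

cfg = iv.SimConfig(seed=1)                      # 97 samples x 50,000 sites
truth, maf = iv.generate_truth(cfg)
imputed = iv.generate_imputed(truth, maf, cfg)

flags = iv.flag_low_confidence(imputed, X=0.9)  # max GP < 0.9 -> low confidence
kept = iv.apply_site_filter(flags, Y=5)         # >= 5 flagged calls removes a site
m = iv.filter_metrics(truth, imputed, kept)
print(f"keep rate {m.keep_rate:.3f}, TPR {m.tpr:.3f}, FPR {m.fpr:.3f}, FDR {m.fdr:.4f}")

tables = iv.confusion_table(truth, imputed, maf)
s = iv.summarize_confusion(iv.pool_tables(tables))
print(f"overall concordance {s.overall_concordance:.3f}, IQS {s.iqs:.3f}, "
      f"non-ref concordance {s.nonref_concordance:.3f}")

em = iv.estimate_error_matrices(
    tables + iv.confusion_table(truth, imputed, maf, site_mask=kept, filtered=True))
for regime in ("true", "imputed", "filtered-imputed"):
    res = iv.required_sample_size(
        iv.DesignConfig(case_maf=0.25, control_maf=0.20, regime=regime), em)
    print(f"{regime:18s} w = {res.w:.4f}  required N = {res.required_n:.0f}")
```

prints

```
keep rate 0.490, TPR 0.853, FPR 0.486, FDR 0.0196
overall concordance 0.935, IQS 0.833, non-ref concordance 0.770
true               w = 0.0791  required N = 6323
imputed            w = 0.0765  required N = 6775
filtered-imputed   w = 0.0767  required N = 6738
```

Reading it: the X = 0.9 / Y = 5 filter keeps 49% of genotype calls on
this rare-skewed cohort while removing 85% of the imputation errors,
leaving 2.0% of the surviving calls discordant. Pooled over all MAF
bins, raw concordance (0.935) flatters the imputation relative to the
chance-corrected IQS (0.833) because rare sites agree by chance. For
a study seeking a case-vs-control MAF difference of 0.25 vs 0.20 at
genome-wide significance, imputation errors shrink the effect size
(w 0.0791 → 0.0765), costing 452 extra samples; quality filtering
claws back part of that.

`run_design_grid(em)` expands the power analysis to 21 case/control
MAF pairs x three case-control ratios x three genotype regimes
(189 configurations); `roc_grid(truth, imputed)` scores the default
7 x 8 filter-threshold grid.

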