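# Methods

`imputeval` quantifies how accurately genotypes imputed from low-pass
(~1x) whole-genome sequencing reproduce a high-coverage truth set, and
translates the observed error structure into case-control study-design
guidance. This note records the statistical model, the defaults and why
they were chosen, the numerical conventions, and what the synthetic
cohort does and does not emulate.

## Data model

Genotypes at normalized biallelic sites are coded 0 (hom-ref), 1 (het),
2 (hom-alt), with missing as -1. Site identity is exact string equality
of (chrom, pos, ref, alt); multiallelic records are split so that each
output allele sees one copy per input copy (total non-reference dosage
is conserved per sample per locus). Half-calls are treated as missing.
Folded minor allele frequency f_min = min(f, 1-f) is computed from
non-missing calls, f = (het + 2*hom-alt) / (2n). All MAF-stratified
statistics use 50 half-open bins (k/100, (k+1)/100]; MAF exactly 0
(invariant, removed upstream) belongs to no bin, MAF 0.5 to the top
bin. MAF can be sourced from the imputed genotypes themselves, the
truth genotypes, or an external reference-panel table — the source is a
parameter everywhere, because in a real low-pass study only the first
and third are available.

## Concordance statistics

For each MAF bin a 3x3 confusion table N counts truth-by-imputed calls
(missing pairs excluded pairwise). From a table with total n:

- observed agreement P_o = tr(N)/n;
- chance agreement P_c = sum_g (row_g * col_g) / n^2;
- imputation quality score IQS = (P_o - P_c) / (1 - P_c).

IQS is exactly Cohen's kappa on the 3x3 table; it corrects for the
allele-frequency-driven chance agreement that inflates raw concordance
at low MAF (a rare variant imputed as hom-ref for everyone still has
high raw concordance but IQS near 0). IQS is undefined when P_c = 1
(single-cell table). Per-genotype rates are row-normalized table rows.
Non-reference concordance defaults to (N11 + N22) / (n - N00); the
alternative convention restricting the denominator to truth-non-ref
calls is available behind a switch, since the literature uses both.
Dosage r^2 is the squared Pearson correlation of the two dosage vectors
per site across samples, then averaged within bin; zero-variance sites
are excluded and counted (pooling calls across sites instead would mix
between-site allele-frequency variance into the correlation, which is
not what array-era imputation r^2 reports).

Group comparisons of per-sample accuracy (reference-panel breeds vs
others) use Welch's unequal-variance t-test with Welch–Satterthwaite
degrees of freedom, two-sided.

## Confidence filtering

A call is low-confidence when max(GP) < X (strict inequality: a call
at exactly the threshold passes). Missing calls and calls without a GP
triplet are flagged. A site is removed when its flagged-call count is
>= Y; equivalently kept iff count < Y, so Y = 0 removes everything.
Published descriptions of this scheme are internally tense: the figure
caption states the >=-removes rule adopted here, while the prose
describes a count threshold of four as "roughly 5%" of 97 samples
(4/97 = 4.1%, 5/97 = 5.2%). We treat Y as the literal count with the
>=-removes rule; the default grids are X in {0.60..0.90 step 0.05}
(7 values) and Y in {1..8}, and the headline filter is X = 0.9 with
Y = 5 (the 5% reading).

Filtering quality is scored over genotype calls, not sites, with
discordant calls as the positives a filter should remove: TPR =
discordant removed / discordant total, FPR = concordant removed /
concordant total, FDR = discordant remaining / calls remaining, keep
rate = calls remaining / calls total. Kept-site sets are nested in Y,
so TPR and FPR are exactly non-increasing in Y at fixed X.

## Error channels and I = G·P

For each MAF bin and filter regime (unfiltered / filtered) the genotype
error channel P is the row-normalized confusion table: P[g, i] is the
probability a true genotype g is imputed as i. 100 matrices cover the
50 bins x 2 regimes. Bins where a genotype row has no observations are
marked unsupported and borrow that row from the nearest supported bin
in the same regime (ties to the lower bin); this preserves the MAF
trend rather than inventing a smooth fit. A row supported nowhere falls
back to identity.

Imputation's effect on genotype counts is the linear push-through
I = G·P with G the 1x3 true counts; expectation mode keeps fractional
counts exact (the default, matching deterministic power curves), and a
seeded multinomial mode resamples each row for uncertainty studies.
Totals are conserved exactly in both.

## Power and required sample size

Association is a Pearson chi-square (df = 1, no continuity correction)
on the 2x2 table of minor-allele **carrier** status (het or hom-alt)
by case/control. Carrier coding is used because the genotype-level
error channel then propagates to the tested variable directly; an
allele-count coding is the main alternative and would require an
additional independence assumption between the two alleles of an
erroneous call. Group genotype counts follow HWE at each group's MAF;
imputed regimes push each group's counts through the channel of the
pooled-MAF bin, where the pooled MAF is the ratio-weighted mean of the
case and control MAFs (the channel depends on the population frequency,
not on phenotype). Effect size is Cohen's
w = sqrt(sum (p_alt - p_null)^2 / p_null) with the null sharing the
pooled carrier frequency across both groups at the configured group
proportions. Power at total size N is the noncentral chi-square upper
tail beyond the central critical value at alpha, with noncentrality
N·w^2 — the same computation as R's `pwr::pwr.chisq.test`. Defaults:
alpha = 5e-8, target power 0.8, N scanned at step 1 over 100..7000
(cheap and removes interpolation ambiguity); required N is the smallest
qualifying N, with NaN as the "not achievable within 7000" sentinel.
The default design grid is the 21 ordered MAF pairs from
{0.05, ..., 0.35} (case > control) crossed with ratios 1:1, 1:3, 3:1
and the three regimes (true, imputed, filtered-imputed); delta-N is
each row's required N minus the true-genotype requirement.

A caution on the "imputation never helps" ordering: it follows from a
data-processing argument only because both groups' genotype
distributions lie on the one-parameter HWE family and realistic
channels are diagonally dominant. For *adversarial* channels and
arbitrary genotype distributions a channel can manufacture carrier
divergence (e.g. one that collapses het to hom-ref applied to groups
with equal carrier but different genotype frequencies), so the
randomized test batteries draw HWE counts and diagonally dominant
channels — the regime the method is defined for.

## Synthetic cohort

The generator exists so every stage runs and is validated end to end
without external data. Defaults are fixed study conditions, not tuning
knobs: 97 samples (the motivating cohort size) x 50,000 independent
sites, site MAFs from 0.5·Beta(0.7, 2.0) (rare-skewed, with support
across all 50 bins), HWE genotypes, invariant draws re-sampled.
Samples cycle through 20 synthetic breeds, half flagged as
reference-panel breeds; non-panel samples' channel off-diagonals are
scaled by 1.3 (a modest representation penalty that makes the
panel-vs-non-panel Welch comparison detectable at n = 97, mirroring
the direction of the published breed effect).

The default channel family sets the per-bin error rate
eps(m) = eps0 + eps1·exp(-m/tau) at the bin center with
eps0 = 0.01, eps1 = 0.15, tau = 0.05, doubled for the het row and
capped at 0.5; off-diagonal mass splits between the two wrong genotypes
in proportion to their HWE frequencies, so rare hets are misimputed
mostly as hom-ref. These values qualitatively reproduce the published
accuracy-vs-MAF shape (poorest for rare heterozygotes) and were chosen
once, not fitted. The filtered regime scales errors by 0.5.

GP triplets: the called genotype is the argmax of its triplet, as in
real imputation output, so its probability lives on [1/3, 1]. It is
drawn from a Beta (concentration `gp_calibration`, default 30) mapped
to that support, with mean equal to the channel's posterior probability
that the call is correct (HWE prior at the site MAF) — raised for
correct calls and lowered for errors by `gp_separation` (default 0.8)
with the overall expectation preserved, so max GP is informative about
correctness both across and within MAF bins. Where the target mean
falls below 1/3 (possible only for error calls) it is floored at the
bottom of the support. The residual splits across the other genotypes
by posterior weight, capped at the called probability. Consequences:
empirical correctness is non-decreasing in max-GP decile, ROC points
sit above the diagonal, and count-threshold filtering removes
error-enriched sites.

The three-dataset overlap generator constructs region sizes exactly
from configured fractions (default: 70% shared by all three, small
pairwise and specific regions) and draws dataset-specific site MAFs
from (0.001, 0.01), pairwise from (0.01, 0.05) and all-shared from
(0.05, 0.5), reproducing the observation that dataset-specific sites
are rare variants.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure (sites are independent — adequate because every
statistic in scope is site-marginal), read-level noise, missingness in
the truth set, indel-specific error modes, or breed-structured allele
frequencies beyond the uniform non-panel error inflation. Passing
tests therefore validate the statistical machinery and its internal
consistency, not imputation performance on real cohorts; the published
headline values (IQS plateaus of 0.91/0.95, ~7M surviving sites,
>500-sample delta-N figures) came from 97 real dogs against a
676-sample proprietary reference panel and are treated as qualitative
shape targets only.

## Numerical conventions and degenerate inputs

- MAF bin lookup rounds to 9 decimals before binning so float noise
  cannot cross a bin edge; delta-MAF values in the design grid are
  rounded to 10 decimals before grouping.
- Percentages in overlap summaries are reported to one decimal.
- GP triplets are written to VCF at 4 decimals; round-trips are exact
  up to that quantization.
- Undefined quantities are flagged, not silently dropped: all-missing
  sites get NaN MAF; zero confusion rows give NaN rates; TPR with no
  discordant calls, r^2 at zero variance, and IQS at P_c = 1 are
  NaN/None; chi-square with a zero marginal raises.
- Statistical tests in the suite run at fixed seeds with 3-sigma (or
  stated absolute) tolerances; the cohort-scale checks use the default
  97 x 50k fixture (~5M calls, seconds to generate), Monte-Carlo power
  checks use 1e5 replicates, and channel-recovery checks use ~1e5
  calls per examined bin.

## Known limitations

- The filtered error channel estimated from a filtered fixture is not
  the parametric filtered channel: it is whatever the filter achieves,
  which at common MAFs is a modest improvement (most errors there sit
  on sites below the removal threshold). Delta-N reductions from
  filtering are therefore smaller on the synthetic cohort than the
  roughly-half reported for the real data.
- Required-N is exact under the expected-counts model; it ignores
  sampling variability of the channel estimate itself.
- Site keys are string-exact; no left-alignment or reference-genome
  validation is attempted.
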