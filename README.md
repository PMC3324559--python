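# eqtlscreen

Two-stage *cis*-eQTL discovery and replication integrated with a two-stage
case-control GWAS, as used to prioritize disease-associated variants by their
effect on gene expression in peripheral blood.

## The problem

Genome-wide association studies of complex diseases pay a heavy
multiple-testing price: true small effects drown among millions of tests.
Because trait-associated SNPs are enriched for expression quantitative trait
loci (eQTLs), one can screen for SNPs that regulate transcript levels in
*cis*, keep those nominally associated with disease, and only carry this
small, biologically anchored set into replication — trading the genome-wide
Bonferroni burden for a correction over a few hundred independent loci.

`eqtlscreen` implements that whole flow as a tested, reusable library:

* **genotype QC** — call rates, MAF, exact Hardy-Weinberg in controls
  (Wigginton-style conditional test), differential missingness,
  heterozygosity outliers, LD pruning, PLINK-style method-of-moments
  relatedness (pi-hat), iterative outlier-removing structure PCA;
* **expression QC** — quantile normalization + log2, PCA outlier arrays, and
  probe hygiene: non-autosomal, non-specific (mapping-hit count ≠ 1) and
  retired probes removed; SNP-in-probe, LD-with-probe-SNP and
  InDel-overlap pair exclusions;
* **covariates** — two-step surrogate-variable analysis (residual SVD with a
  Buja–Eyuboglu permutation test) plus status-associated genotype PCs;
* ***cis*-eQTL mapping** — per-pair OLS of expression on additive dosage
  within ±500 kb of the probe midpoint, with significance called by
  **permutation-anchored empirical FDR**: whole genotype vectors are
  reassigned to random subjects (expression, status and covariates stay
  put), preserving LD and expression correlation in the null;
* **GWAS integration** — per-SNP logistic regression (IRLS) with
  genomic-control λ, eQTL prioritization at nominal GWAS p < 0.05,
  MAF-matched permutation enrichment, replication, greedy LD clumping
  (r² > 0.5) and Bonferroni correction over the clump count;
* **power** — two-proportion allelic sample-size formula with a Monte-Carlo
  verification;
* **synthetic data** — a seeded generator (founder-haplotype LD blocks,
  Balding–Nichols population drift, logistic disease model, planted cis
  effects and probe artifacts) so every stage is testable offline.

## The model in brief

For a cis pair (SNP *g*, probe *y*) with covariates *C* (status, age, sex,
riluzole use, surrogate variables):

&nbsp;&nbsp;&nbsp;&nbsp;*y* = β·*g* + *C*γ + ε,&nbsp;&nbsp;ε ~ N(0, σ²)

tested by the t-statistic on β. With M testable cis combinations, the
empirical FDR at a p-value threshold *t* is
(mean permutation count of p ≤ *t*) / (observed count of p ≤ *t*),
and the significance threshold is the largest observed p with empirical
FDR ≤ 5% (Benjamini–Hochberg q-values over M are reported alongside).
Disease association per SNP is logit P(case) = α + β·*g* + covariates, with
Wald tests, λ = median(χ²)/0.4549, and a final Bonferroni correction by the
number of LD clumps.

## Worked example

`examples/07_two_stage_pipeline.py` plants one SNP that is both a strong
cis eQTL (β = 1.5 SD per allele) and a risk SNP (OR 1.8) across four
simulated cohorts, then runs the complete flow:

```
planted eQTL+risk SNP: rs000494
...
cis_pairs_testable: 5951
eqtl_discovery_significant_pairs: 6
gwas_discovery_lambda: 0.915
selected_pairs: 1
replicated_pairs: 1
gwas_replication_snps_tested: 1
n_clumps: 1
final_loci: 1

final Bonferroni-surviving loci:
index_snp  index_p   p_bonf
 rs000494 0.018289 0.018289
```

The planted SNP survives every stage — eQTL FDR, nominal GWAS association,
eQTL replication, GWAS replication, clumping — and is the unique final
locus. `examples/` contains one script per capability (simulation, genotype
QC, expression/probe hygiene, cis scan, GWAS+clumping, power), each printing
what it computes and what the numbers mean. A thin CLI covers shell use:
`eqtlscreen simulate`, `eqtlscreen run`, `eqtlscreen power`.

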