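# Methods

## Scope and data model

`eqtlscreen` implements a two-stage expression-anchored association screen:
an eQTL discovery cohort (genotypes + array expression), an eQTL replication
cohort, and two genotype-only GWAS cohorts. Genotypes are held as a dense
samples × SNPs minor-allele dosage matrix ({0,1,2}, NaN for missing calls)
with SNP/sample metadata; expression, annotation, covariate and result
tables are pandas DataFrames. Genomic coordinates are 1-based inclusive
(the PLINK BIM convention); *cis* means |SNP position − probe midpoint|
≤ 500 kb (a 1 Mb window), with an inclusive boundary. SNP-anchored locus
fine-mapping uses a strict < 500 kb distance, matching the way locus pair
counts are usually quoted.

## Synthetic-data generator

The generator is first-class, tested code: it defines the conditions under
which every downstream guarantee is demonstrated.

**Genotypes.** SNPs are laid out in contiguous runs per chromosome
(default spacing 5 kb) and grouped into LD blocks of `block_size` SNPs
(blocks never span chromosomes). Per block, ancestral allele frequencies are
drawn uniformly from `maf_range` (default 0.05–0.5); a pool of
`n_founder_haplotypes` (default 20) haplotypes is sampled, and each
individual receives two pool haplotypes drawn independently with
replacement. This yields within-block LD of order 1/H, between-block
independence, and exact Hardy–Weinberg proportions conditional on the pool.
Two subpopulations (fraction `admix_fraction` in the second) get separate
pools drawn from Balding–Nichols-drifted frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F) with F = `fst` (default 0.01, a mild
European-scale differentiation). At `fst = 0` a single shared pool is used —
with separate finite pools, pool-sampling noise alone would act as drift and
produce PCA-visible structure where none is configured. For `fst > 0`, the
finite pool adds its own sampling noise on top of the nominal F; the
realized differentiation is therefore slightly larger than the parameter.
The frequency each SNP was actually sampled from is recorded
(`gen_freq`) so allele-frequency recovery is testable; dosages are recoded
so the coded allele is the minor allele observed in the sample.

**Phenotype.** Case/control status is Bernoulli with
logit = b₀ + Σ log(OR)·g over `n_risk_snps` designated risk SNPs
(per-allele odds ratio `risk_or`); b₀ is solved so the expected case
fraction matches n_cases/(n_cases+n_controls). Cohort sizes default to the
blood-expression study this package models (162/207 cases/controls per eQTL
stage); GWAS-stage defaults (1,000/1,400 per stage) are a genotype-only
cohort at replication scale.

**Expression.** On a log2-like scale: probe baseline N(8,1) + batch offset
(per batch × probe, SD `batch_sd`) + `cis_beta`·dosage at planted pairs +
N(0,1) noise, then exponentiated (2^x) to strictly positive raw
intensities so the normalization stage operates on realistic input. Effects
are in residual-SD units, so the expected model R² is analytic:
R² = β²·Var(g)/(β²·Var(g)+1). Planted cis SNPs are drawn from segregating
SNPs (sample MAF ≥ 0.05) — an eQTL on a monomorphic SNP is no eQTL — and
their probes are placed within ±200 kb of the SNP. `n_overlap_risk_cis`
makes leading risk SNPs double as cis SNPs for end-to-end positives.

**Artifacts.** Disjoint probe sets are flagged non-autosomal (chromosome
"X", present only to be filtered), non-specific (0 or ≥2 genomic mapping
hits), retired, SNP-in-probe (the probe interval is relocated onto a SNP
position), or InDel-overlapped (a matching InDel row is emitted). When
`artifact_counts` is not given, counts are derived from `n_probes` at
array-realistic fractions (4.1% / 14.8% / 5% / 2% / 2.5%) matching the
proportions reported for the HumanHT-12-style annotation this emulates.

**What the generator does not emulate:** realistic human haplotype maps or
recombination hotspots, allele-frequency spectra skewed toward rare
variants, genotyping batch effects, probe GC/intensity biases, or
trans-regulation. Tests passing under these conditions demonstrate the
statistical machinery controls its error rates under the stated model, not
performance on any particular real cohort.

## Genotype QC

The cascade runs in a fixed order so reports are reproducible: sample call
rate (< 0.95 removed) → SNP call rate (< 0.95) → MAF (< 0.05) → exact HWE in
controls (p < 1e-4) → case/control differential missingness → per-sample
heterozygosity outliers. Differential missingness is a 1-df Pearson
chi-square on the called/missing × case/control table, excluded at p < 1e-4
(mirroring the HWE stringency; the convention is ours). Heterozygosity uses
mean ± 3 SD of per-sample autosomal heterozygosity. Note the relative
(± k SD) criterion is not idempotent by construction — recomputing it on its
own output can always trim another tail — so the cascade is a fixed point of
itself only with that criterion disabled; the SNP-level filters are exactly
idempotent.

The HWE test is the exact conditional test: the probability of each
heterozygote count given the allele counts, summing all outcomes no more
probable than the observed one (log-gamma arithmetic, normalized in place;
ties included with a 1e-12 relative tolerance). It agrees with exhaustive
integer enumeration for all tables with n ≤ 30.

**Relatedness.** PLINK-style method of moments: per pair, observed IBS0/1/2
counts over co-called SNPs are compared with their expectations under
IBD = 0/1/2 given sample allele frequencies; P(IBD=0) = IBS0/E[IBS0|IBD0],
P(IBD=1) from the IBS1 excess, P(IBD=2) as remainder;
pi-hat = P(IBD=1)/2 + P(IBD=2), truncated to [0,1]. The finite-sample
bias-correction factors PLINK applies to the expectations are omitted; at
the SNP counts used here the estimator recovers duplicates (pi-hat ≈ 1),
full sibs (≈ 0.5 ± 0.1) and unrelated pairs (≈ 0 ± 0.05), which is what the
pi-hat > 0.2 screen needs. Of a flagged pair, the lower-call-rate member is
listed for removal.

**Structure PCA.** Columns standardized by mean 2p and √(2p(1−p)) (missing
→ 0 after centering; monomorphic columns dropped), truncated SVD, samples
beyond 6 SD on any retained axis removed, recomputed up to 5 rounds —
the EIGENSTRAT defaults. LD r² throughout the package is the squared
Pearson correlation of dosages (composite LD on unphased genotypes); the
original analyses used phased reference panels for some LD lookups, which
are out of scope here.

## Expression QC

Quantile normalization maps each sample's rank-r value to the mean of the
r-th order statistics across samples; tied values receive the mean of the
reference values their tied ranks span (the common convention), then log2.
Outlier arrays are samples beyond 4 SD on expression PC1/PC2, iterated to
stability; below 10 samples the step warns and does nothing. Probe filters
run in order — non-autosomal, mapping_hits ≠ 1 ("no or multiple" genomic
hits, the BLAT-specificity criterion abstracted into the annotation input),
retired — with per-step counts reported. The pipeline normalizes once for
outlier detection, trims samples and probes, and re-normalizes the trimmed
raw matrix.

Pair exclusions: SNPs inside a probe's interval (snp_in_probe); SNPs whose
dosage r² with any in-probe SNP of that probe exceeds 0.2, searched within
the cis window (ld_with_probe_snp); and, for probes overlapped by an InDel,
all of the probe's cis pairs (indel_overlap). The probe-level reading of the
InDel rule was chosen over an LD-mediated one because it matches how
excluded combination counts are tallied; it is the more conservative of the
two. The exclusion set is monotone: lowering the LD threshold only grows it.

## Covariates

Surrogate variables: each probe is regressed on the known covariates
(status, age, sex, riluzole — status included deliberately, so the SVs are
estimated protecting the disease signal), the residual matrix is
SVD-decomposed, and component k is retained while its variance share
exceeds the permutation distribution of the k-th share (each probe's
residuals permuted independently, re-residualized; n_perm = 20, add-one
p ≤ 0.05, stopping at the first failure). This is the two-step variant:
reproducible, deterministic given the seed, orthonormal output. The number
of SVs is data-dependent by design and is estimated per dataset, never
fixed. GWAS covariates: sex + cohort dummies + whichever of the top 10
genotype PCs associate with status at p < 0.05 in univariate logistic
regressions.

## cis-eQTL mapping and permutation FDR

Per pair, OLS of probe expression on dosage + covariates over samples with
a non-missing call for that SNP (complete-case); t-test on the dosage
coefficient; model R² = 1 − RSS/TSS. Pairs with constant dosage or fewer
samples than parameters are skipped with a reason. When a SNP has no
missing calls the fit uses the Frisch–Waugh residualization fast path,
which is algebraically identical to the full regression (verified against
statsmodels to 1e-8).

The permutation null reassigns whole genotype vectors to random subjects;
expression, status and all covariates stay with the subject. This preserves
between-SNP LD and between-probe correlation exactly, which is what makes
the pooled permutation p-values an honest null for the correlated test
family. Within each permutation, dosages are residualized against the
covariates after the reassignment. Two numerical choices: (i) missing
dosages are mean-imputed inside the permutation scan (the observed fits
remain complete-case) — at the default 1% missingness this perturbs null
p-values negligibly and keeps a 100-permutation scan a few matrix products;
(ii) the permutation count at a threshold is add-one smoothed
((count+1)/n_perm), so the empirical FDR never reports exactly zero and the
significant set empties as the target FDR → 0. The significance threshold
is the largest observed p with empirical FDR ≤ the target; BH q-values
computed against the full testable pair count M are reported alongside, as
the two corrections answer slightly different questions and the design
quotes both. Default n_perm is 10,000; the test suite and examples use
50–100 permutations, which is the same estimator at coarser resolution.

Replication refits only the selected pairs in the replication cohort (its
own SVs and covariates) and calls significance with the same permutation
caller, with M equal to the selected-pair count. Locus fine-mapping
restricts pairs to a SNP-anchored (< 500 kb to midpoint) or region-anchored
locus and applies per-locus BH at 5%; with one pair this reduces to
p ≤ 0.05.

## GWAS integration

Logistic regression per SNP by Newton/IRLS (tolerance 1e-8, ≤ 25
iterations), Wald test on the dosage coefficient. Separation and
non-convergence are detected (diverging coefficients, exploding SEs) and
flagged rather than fatal; flagged SNPs carry missing p and are excluded
from λ = median(χ²)/0.4549. With a single binary predictor the MLE equals
the 2×2 cross-product odds ratio (tested to 1e-6).

Enrichment: observed = |{associated SNPs} ∩ {eQTL SNPs}|; each permutation
draws, from the non-associated SNPs without replacement, a set matching the
associated set's per-0.05-MAF-bin counts and counts its eQTL members.
Within a bin that count is hypergeometric, so permutations are generated
bin-wise from the hypergeometric distribution — identical in law to literal
resampling and fast enough for 100,000 permutations. Empirical
p = (1 + #{perm ≥ observed})/(1 + n_perm); the add-one form avoids p = 0.
A bin needing more matches than the negative set can supply is an error
naming the bin.

Clumping is greedy: the unassigned SNP with the smallest p (ties broken by
chromosome, then position) indexes a clump that absorbs all unassigned SNPs
within ±1 Mb with r² > 0.5. The window is deliberately wide (PLINK's 250 kb
default is narrower) so "independent loci" errs conservative — fewer, larger
clumps mean a smaller Bonferroni factor claimed. Clumps partition the tested
SNPs; each index p is corrected by min(1, p × #clumps) and loci under 0.05
are final. Joint two-stage association pools the cohorts with a
stage-indicator covariate (covariate columns aligned by name); a
fixed-effect inverse-variance meta-analysis of the per-stage estimates is
available as `method="meta"`, since a pooled refit and a meta-analysis are
both defensible readings of a "joint" analysis.

Power: two-proportion chi-square on allele counts without continuity
correction; p₁ = OR·p₀/(1+p₀(OR−1)); allele count per group
(z₁₋α/2·√(2p̄q̄) + z_power·√(p₀q₀+p₁q₁))²/(p₁−p₀)²; persons = ⌈alleles/2⌉.
A Monte-Carlo oracle (binomial allele counts, allelic chi-square) verifies
the returned n delivers 0.78–0.84 empirical power at the 0.80 target.

## Problem sizes

The test suite and acceptance checks run the machinery at desk scale, chosen
as the smallest sizes at which each property is statistically decisive:
2,000 samples × 2,000 SNPs for HWE calibration; 5,000 SNPs × 800 samples
for λ; 400 samples for effect recovery; 20-seed batches for FDR and
end-to-end null control; 200 runs for enrichment calibration; four cohorts
of 300 (expression) and 800 (GWAS) samples over 600 SNPs / 80 probes for
the planted end-to-end run. Defaults in the API remain at study scale
(10,000 permutations, 100,000 enrichment draws).

## Known limitations

* The permutation scan's mean-imputation shortcut (above) makes the null
  marginally conservative at high missingness; beyond ~5% missing calls,
  prefer complete-data genotypes for the eQTL stage.
* Pi-hat omits PLINK's finite-sample corrections and can be noisy below
  ~500 pruned SNPs (a warning fires below 50).
* The generator's LD is exchangeable within blocks — clumping and pruning
  see realistic r² magnitudes but not distance-decaying LD.
* Trans-eQTLs, conditional/multi-SNP models, imputation, X-chromosome
  analysis and multi-platform cohort merging are out of scope.
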