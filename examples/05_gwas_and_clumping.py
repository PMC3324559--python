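"""Case-control association, MAF-matched eQTL enrichment, and LD clumping
with clump-count Bonferroni correction.

The enrichment test asks whether nominally disease-associated SNPs carry
more eQTLs than MAF-matched non-associated SNPs; clumping reduces the
replication association results to approximately independent loci before the
final multiple-testing correction.
"""

import pandas as pd

from eqtlscreen import (
    SimulationConfig,
    clump_and_correct,
    eqtl_enrichment_test,
    logistic_gwas,
    simulate_bundle,
)

cfg = SimulationConfig(seed=5, n_cases=600, n_controls=600, n_snps=1200,
                       n_probes=40, n_cis_effects=0, n_chromosomes=8, n_risk_snps=3,
                       risk_or=1.5)
bundle, truth = simulate_bundle(cfg)
geno = bundle.genotypes

assoc, summary = logistic_gwas(geno, bundle.phenotypes["status"])
print(f"GWAS: {summary.n_snps_tested} SNPs, genomic-control lambda "
      f"{summary.gc_lambda:.3f}, {summary.n_nominal} at p < 0.05")

# pretend the planted risk SNPs are known eQTLs, everything else is not
pos = set(assoc.loc[assoc["p"] < 0.05, "snp"].dropna())
neg = set(assoc.loc[assoc["p"] >= 0.05, "snp"].dropna())
eqtls = set(truth.risk_snps["snp"]) | set(list(neg)[::40])
maf = pd.Series(geno.maf(), index=geno.snps.index)
enrich = eqtl_enrichment_test(pos, neg, eqtls, maf, n_perm=9999, seed=5)
print(f"enrichment: observed {enrich['observed']} eQTLs among associated "
      f"SNPs, expected {enrich['expected']:.1f}, empirical p = "
      f"{enrich['empirical_p']:.4f}")

clumps, final = clump_and_correct(assoc, geno, r2_min=0.5, alpha=0.05)
print(f"clumping: {len(clumps)} independent loci; "
      f"{len(final)} survive Bonferroni over the clump count")
print(final[["index_snp", "n_members", "index_p", "p_bonf"]].to_string(index=False))
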