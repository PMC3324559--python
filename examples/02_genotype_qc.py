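"""Genotype quality control: the SNP/sample cascade, LD pruning, relatedness
and structure PCA.

Each printed count is a filter step; pi-hat is the estimated genome fraction
shared identical-by-descent (1 for duplicates, ~0.5 for full sibs), and PC1
of the genotype PCA separates the two simulated subpopulations.
"""

import numpy as np

from eqtlscreen import (
    QcThresholds,
    SimulationConfig,
    estimate_relatedness,
    ld_prune,
    pca_structure,
    qc_genotypes,
    simulate_bundle,
)

cfg = SimulationConfig(seed=2, n_cases=150, n_controls=150, n_snps=1500,
                       n_probes=40, n_cis_effects=0, n_chromosomes=10, fst=0.08,
                       admix_fraction=0.4, missing_rate=0.02)
bundle, _ = simulate_bundle(cfg)
geno = bundle.genotypes

clean, report = qc_genotypes(geno, QcThresholds())
for criterion, ids in report.removed.items():
    print(f"removed by {criterion}: {len(ids)}")
print(f"kept: {clean.n_samples} samples, {clean.n_snps} SNPs")

pruned = ld_prune(clean, window_snps=50, step=5, r2_max=0.2)
print(f"LD pruning: {clean.n_snps} -> {len(pruned)} SNPs in approximate equilibrium")

pairs, removal = estimate_relatedness(clean.subset_snps(pruned), pihat_max=0.2)
print(f"relatedness: max pi-hat {pairs['pi_hat'].max():.3f}, "
      f"{len(removal)} samples flagged for removal")

pca = pca_structure(clean.subset_snps(pruned))
sub = clean.samples.loc[pca.coordinates.index, "subpop"]
r = np.corrcoef(pca.coordinates["PC1"], sub)[0, 1]
print(f"PCA: {pca.coordinates.shape[1]} axes, {len(pca.outliers)} outliers removed, "
      f"|corr(PC1, subpopulation)| = {abs(r):.2f}")
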