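"""The full two-stage flow on four simulated cohorts.

One SNP is planted as both a strong cis eQTL and a risk SNP, so it should
survive every stage: eQTL discovery FDR -> nominal GWAS association ->
eQTL replication FDR -> GWAS replication -> LD clumping -> Bonferroni over
the clump count.  The per-stage counts mirror the study-design diagram of a
two-stage expression-anchored association screen.
"""

from eqtlscreen import PipelineParams, run_two_stage, write_reports
from eqtlscreen.simulate import SimulationConfig, simulate_two_stage_bundles

cfg = SimulationConfig(
    seed=21,
    n_cases=150, n_controls=150,          # per eQTL stage (expression + genotypes)
    n_gwas_cases=400, n_gwas_controls=400,  # per GWAS stage (genotypes only)
    n_snps=600, n_probes=80, n_chromosomes=6,
    n_cis_effects=4, cis_beta=1.5,
    n_risk_snps=2, risk_or=1.8,
    n_overlap_risk_cis=1,                 # one SNP is both eQTL and risk SNP
    missing_rate=0.01,
    artifact_counts={"non_autosomal": 3, "non_specific": 5, "retired": 3,
                     "snp_in_probe": 2, "indel_overlap": 2},
)
bundles, truth = simulate_two_stage_bundles(cfg)
print(f"planted eQTL+risk SNP: {truth.risk_snps['snp'].iloc[0]}")

params = PipelineParams(n_perm_eqtl=100, n_perm_enrichment=1000, seed=21)
report = run_two_stage(bundles, params)

for stage, value in report.counts.items():
    print(f"{stage}: {value}")

final = report.tables["final_loci"]
if len(final):
    print("\nfinal Bonferroni-surviving loci:")
    print(final[["index_snp", "index_p", "p_bonf"]].to_string(index=False))

paths = write_reports(report, "scratch/example_run")
print(f"\nreports written: {sorted(p.name for p in paths.values())}")
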