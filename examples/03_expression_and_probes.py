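"""Expression normalization and probe hygiene.

Quantile normalization forces every array onto the same intensity
distribution before log2; the probe filters then drop non-autosomal,
non-specific (0 or >1 genomic mapping hits) and retired probes, and the
pair-exclusion list removes SNP-probe combinations where a variant inside
the probe's target sequence (or an LD partner, or an overlapping InDel)
could fake a cis signal.
"""

import numpy as np

from eqtlscreen import (
    SimulationConfig,
    build_pair_exclusions,
    detect_outlier_arrays,
    filter_probes,
    quantile_normalize_log2,
    simulate_bundle,
)

cfg = SimulationConfig(
    seed=3, n_cases=120, n_controls=120, n_snps=800, n_probes=200,
    n_chromosomes=6,
    artifact_counts={"non_autosomal": 8, "non_specific": 30, "retired": 10,
                     "snp_in_probe": 6, "indel_overlap": 5},
)
bundle, _ = simulate_bundle(cfg)

norm = quantile_normalize_log2(bundle.expression)
sorted_rows = np.sort(norm.to_numpy(), axis=1)
print(f"after normalization every array has the same sorted profile: "
      f"{np.allclose(sorted_rows, sorted_rows[0])}")

_, flagged = detect_outlier_arrays(norm, sd_cut=4.0)
print(f"outlier arrays flagged: {len(flagged)}")

kept, report = filter_probes(bundle.probe_annotation)
print(f"probe filters: start {report.start}, removed {report.removed}, "
      f"kept {report.kept}")

excl = build_pair_exclusions(bundle.genotypes, bundle.probe_annotation.loc[kept],
                             bundle.indels, r2_ld=0.2)
print("pair exclusions by reason:")
print(excl["reason"].value_counts().to_string())
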