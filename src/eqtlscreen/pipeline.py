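"""End-to-end two-stage study flow.

QC -> normalize/filter -> covariates (SVA, genotype PCs) -> eQTL discovery
(permutation FDR) -> GWAS discovery -> prioritize (nominal GWAS p) ->
MAF-matched enrichment -> eQTL replication (FDR) -> GWAS replication on
replicated eQTL SNPs -> LD clumping -> clump-count Bonferroni -> final loci.
Per-step pair/SNP counts are recorded so a run report mirrors the study
design diagram.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import pandas as pd

from .core import StudyBundle
from .covariates import assemble_covariates, estimate_surrogate_variables
from .eqtl import call_significant_eqtls, enumerate_cis_pairs, map_cis_eqtls
from .expression_qc import (
    build_pair_exclusions,
    detect_outlier_arrays,
    filter_probes,
    quantile_normalize_log2,
)
from .genotype_qc import QcThresholds, estimate_relatedness, ld_prune, pca_structure, qc_genotypes
from .gwas import (
    clump_and_correct,
    eqtl_enrichment_test,
    logistic_gwas,
    prioritize_eqtls,
    replicate_eqtls,
)

log = logging.getLogger("eqtlscreen")


@dataclass
class PipelineParams:
    qc: QcThresholds = field(default_factory=QcThresholds)
    half_window: int = 500_000
    eqtl_fdr: float = 0.05
    n_perm_eqtl: int = 10_000
    gwas_p_cut: float = 0.05
    pair_exclusion_r2: float = 0.2
    enrichment_bin_width: float = 0.05
    n_perm_enrichment: int = 100_000
    clump_r2: float = 0.5
    clump_window: int = 1_000_000
    final_alpha: float = 0.05
    sva_n_perm: int = 20
    sva_alpha: float = 0.05
    pc_select_p: float = 0.05
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.2
    expr_sd_cut: float = 4.0
    pca_axes: int = 10
    pca_outlier_sd: float = 6.0
    seed: int = 0


@dataclass
class RunReport:
    counts: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)
    incomplete: list = field(default_factory=list)
    seed: int = 0


def run_two_stage(bundles: dict[str, StudyBundle], params: PipelineParams | None = None) -> RunReport:
    """Execute the full two-stage flow on four bundles.

    ``bundles`` keys: ``eqtl_discovery``, ``eqtl_replication``,
    ``gwas_discovery``, ``gwas_replication``.  Any stage failure aborts with
    the stage name and cause.
    """
    params = params or PipelineParams()
    required = {"eqtl_discovery", "eqtl_replication", "gwas_discovery", "gwas_replication"}
    missing = required - set(bundles)
    if missing:
        raise ValueError(f"missing bundles: {sorted(missing)}")
    report = RunReport(seed=params.seed)

    def _stage(name):
        def wrap(fn, *args, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kw)
            except Exception as e:
                raise RuntimeError(f"stage '{name}' failed: {e}") from e
            log.info("stage %s: %.2fs", name, time.perf_counter() - t0)
            return out

        return wrap

    # ---- eQTL-side preparation (both expression stages)
    eqtl_prepped = {}
    for stage_name in ("eqtl_discovery", "eqtl_replication"):
        eqtl_prepped[stage_name] = _stage(f"prepare_{stage_name}")(
            _prepare_expression_stage, bundles[stage_name], params
        )
        prep = eqtl_prepped[stage_name]
        report.counts[f"{stage_name}_samples"] = prep["geno"].n_samples
        report.counts[f"{stage_name}_snps"] = prep["geno"].n_snps
        report.counts[f"{stage_name}_probes_kept"] = len(prep["kept_probes"])

    # ---- eQTL discovery scan
    prep = eqtl_prepped["eqtl_discovery"]
    pairs, M = _stage("enumerate_cis_pairs")(
        enumerate_cis_pairs,
        prep["geno"].snps,
        prep["annot"].loc[prep["kept_probes"]],
        params.half_window,
        prep["exclusions"],
    )
    report.counts["cis_pairs_testable"] = M
    results = _stage("eqtl_discovery_scan")(
        map_cis_eqtls, prep["geno"], prep["expr"], prep["covs"].eqtl, pairs
    )
    call = _stage("eqtl_discovery_fdr")(
        call_significant_eqtls,
        results,
        prep["geno"],
        prep["expr"],
        prep["covs"].eqtl,
        M,
        n_perm=params.n_perm_eqtl,
        fdr=params.eqtl_fdr,
        seed=params.seed,
    )
    report.tables["eqtl_discovery"] = call.results
    report.counts["eqtl_discovery_significant_pairs"] = len(call.significant)

    # ---- GWAS discovery
    gd_geno, gd_covs = _stage("prepare_gwas_discovery")(
        _prepare_gwas_stage, bundles["gwas_discovery"], params
    )
    gwas_disc, disc_summary = _stage("gwas_discovery_scan")(
        logistic_gwas, gd_geno, gd_geno.samples["status"], gd_covs.gwas, "discovery"
    )
    report.tables["gwas_discovery"] = gwas_disc
    report.counts["gwas_discovery_snps"] = disc_summary.n_snps_tested
    report.counts["gwas_discovery_lambda"] = round(disc_summary.gc_lambda, 4)
    report.counts["gwas_discovery_nominal"] = disc_summary.n_nominal

    # ---- prioritize eQTL pairs by nominal GWAS association
    selected, selected_snps = _stage("prioritize")(
        prioritize_eqtls, call.significant, gwas_disc, params.gwas_p_cut
    )
    report.tables["selected_pairs"] = selected
    report.counts["selected_pairs"] = len(selected)
    report.counts["selected_snps"] = len(selected_snps)

    # ---- enrichment of eQTLs among associated SNPs
    ok = gwas_disc.dropna(subset=["p"])
    pos = set(ok.loc[ok["p"] < params.gwas_p_cut, "snp"])
    neg = set(ok.loc[ok["p"] >= params.gwas_p_cut, "snp"])
    eqtl_snp_set = set(call.significant["snp"])
    maf = pd.Series(gd_geno.maf(), index=gd_geno.snps.index)
    if pos and neg:
        enrich = _stage("enrichment")(
            eqtl_enrichment_test,
            pos,
            neg,
            eqtl_snp_set,
            maf,
            bin_width=params.enrichment_bin_width,
            n_perm=params.n_perm_enrichment,
            seed=params.seed,
        )
        report.counts["enrichment_observed"] = enrich["observed"]
        report.counts["enrichment_expected"] = round(enrich["expected"], 2)
        report.counts["enrichment_empirical_p"] = enrich["empirical_p"]
    else:
        report.incomplete.append("enrichment")

    # ---- eQTL replication
    prep_r = eqtl_prepped["eqtl_replication"]
    replicated, dropped = _stage("eqtl_replication")(
        replicate_eqtls,
        selected,
        prep_r["geno"],
        prep_r["expr"],
        prep_r["covs"].eqtl,
        fdr=params.eqtl_fdr,
        n_perm=params.n_perm_eqtl,
        seed=params.seed,
    )
    report.tables["replicated_pairs"] = replicated
    report.counts["replicated_pairs"] = len(replicated)
    replicated_snps = pd.Index(pd.unique(replicated["snp"])) if len(replicated) else pd.Index([])
    report.counts["replicated_snps"] = len(replicated_snps)

    # ---- GWAS replication on the replicated eQTL SNPs
    gr_geno, gr_covs = _stage("prepare_gwas_replication")(
        _prepare_gwas_stage, bundles["gwas_replication"], params
    )
    test_snps = replicated_snps.intersection(gr_geno.snps.index)
    report.counts["gwas_replication_snps_tested"] = len(test_snps)
    if len(test_snps):
        sub = gr_geno.subset_snps(test_snps)
        gwas_rep, _ = _stage("gwas_replication_scan")(
            logistic_gwas, sub, sub.samples["status"], gr_covs.gwas, "replication"
        )
        report.tables["gwas_replication"] = gwas_rep
        clumps, final = _stage("clump_and_correct")(
            clump_and_correct,
            gwas_rep,
            sub,
            r2_min=params.clump_r2,
            window=params.clump_window,
            alpha=params.final_alpha,
        )
        report.tables["clumps"] = clumps
        report.tables["final_loci"] = final
        report.counts["n_clumps"] = len(clumps)
        report.counts["final_loci"] = len(final)
    else:
        report.counts["n_clumps"] = 0
        report.counts["final_loci"] = 0
        report.incomplete += ["gwas_replication", "clumping"]
    return report


# --------------------------------------------------------------------------- #
# stage preparation
# --------------------------------------------------------------------------- #

def _prepare_expression_stage(bundle: StudyBundle, params: PipelineParams) -> dict:
    geno, _ = qc_genotypes(bundle.genotypes, params.qc)
    norm1 = quantile_normalize_log2(bundle.expression.loc[bundle.expression.index.intersection(geno.samples.index)])
    _, outliers = detect_outlier_arrays(norm1, sd_cut=params.expr_sd_cut)
    kept_samples = norm1.index.difference(pd.Index(outliers), sort=False)

    kept_probes, _ = filter_probes(bundle.probe_annotation)
    raw_trim = bundle.expression.loc[kept_samples, kept_probes]
    expr = quantile_normalize_log2(raw_trim)

    common = geno.samples.index.intersection(expr.index).sort_values()
    geno = geno.subset_samples(common)
    expr = expr.loc[common]
    pheno = bundle.phenotypes.loc[common]

    exclusions = build_pair_exclusions(
        geno,
        bundle.probe_annotation.loc[kept_probes],
        bundle.indels,
        r2_ld=params.pair_exclusion_r2,
        half_window=params.half_window,
    )

    known = pheno[[c for c in ("status", "age", "sex", "riluzole") if c in pheno.columns]]
    svs = estimate_surrogate_variables(
        expr, known, n_perm=params.sva_n_perm, alpha=params.sva_alpha, seed=params.seed
    )
    pca = pca_structure(geno, n_axes=min(params.pca_axes, geno.n_samples - 2),
                        outlier_sd=params.pca_outlier_sd)
    pcs = pca.coordinates.reindex(common).fillna(0.0)
    covs = assemble_covariates(pheno, pcs, svs, pc_select_p=params.pc_select_p)
    return {
        "geno": geno,
        "expr": expr,
        "annot": bundle.probe_annotation,
        "kept_probes": kept_probes,
        "exclusions": exclusions,
        "covs": covs,
        "pheno": pheno,
    }


def _prepare_gwas_stage(bundle: StudyBundle, params: PipelineParams):
    geno, _ = qc_genotypes(bundle.genotypes, params.qc)
    pruned = ld_prune(geno, params.prune_window, params.prune_step, params.prune_r2)
    _, to_remove = estimate_relatedness(geno.subset_snps(pruned), pihat_max=params.qc.pihat_max)
    geno = geno.drop_samples(to_remove)
    pca = pca_structure(
        geno.subset_snps(pruned),
        n_axes=min(params.pca_axes, geno.n_samples - 2),
        outlier_sd=params.pca_outlier_sd,
    )
    geno = geno.subset_samples(pca.coordinates.index)
    pheno = bundle.phenotypes.loc[geno.samples.index]
    covs = assemble_covariates(pheno, pca.coordinates, None, pc_select_p=params.pc_select_p)
    return geno, covs
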