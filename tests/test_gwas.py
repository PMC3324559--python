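"""Logistic association scan, eQTL prioritization/enrichment, replication,
LD clumping with clump-count Bonferroni, and the power calculation."""

import numpy as np
import pandas as pd
import pytest

from eqtlscreen.core import GenotypeMatrix
from eqtlscreen.eqtl import call_significant_eqtls, enumerate_cis_pairs, map_cis_eqtls
from eqtlscreen.expression_qc import quantile_normalize_log2
from eqtlscreen.gwas import (
    PowerQuery,
    bonferroni_correct,
    clump_and_correct,
    empirical_power,
    eqtl_enrichment_test,
    logistic_gwas,
    prioritize_eqtls,
    replicate_eqtls,
    required_sample_size,
)
from eqtlscreen.simulate import (
    simulate_bundle,
    simulate_genotypes,
    simulate_phenotype_and_expression,
)

from conftest import small_config


def _single_snp_geno(x, y):
    n = len(x)
    return GenotypeMatrix(
        np.asarray(x, dtype=float)[:, None],
        pd.DataFrame({"chrom": ["1"], "pos": [1000], "a1": ["A"], "a2": ["G"]},
                     index=pd.Index(["rs1"], name="snp")),
        pd.DataFrame({"status": y}, index=pd.Index([f"S{i:04d}" for i in range(n)],
                                                   name="sample")),
    )


# --------------------------------------------------------------------------- #
# logistic scan
# --------------------------------------------------------------------------- #

def test_covariate_free_binary_dosage_equals_cross_product_or():
    rng = np.random.default_rng(0)
    x = rng.integers(0, 2, 400).astype(float)
    y = (rng.random(400) < 1 / (1 + np.exp(-(-0.4 + 0.9 * x)))).astype(int)
    geno = _single_snp_geno(x, y)
    table, _ = logistic_gwas(geno, pd.Series(y, index=geno.samples.index))
    a = ((x == 1) & (y == 1)).sum()
    b = ((x == 1) & (y == 0)).sum()
    c = ((x == 0) & (y == 1)).sum()
    d = ((x == 0) & (y == 0)).sum()
    assert table["or"].iloc[0] == pytest.approx(a * d / (b * c), abs=1e-6)


def test_null_scan_lambda_near_one():
    """Genomic-control lambda on a null scan of 5,000 SNPs: the single-draw
    median has sd ~0.03 under block LD, so average three status draws."""
    cfg = small_config(seed=7, n_snps=5000, n_chromosomes=22, n_probes=10)
    geno = simulate_genotypes(cfg, n_samples=800)
    lams = []
    for s in (1, 2, 3):
        status = pd.Series(np.random.default_rng(s).integers(0, 2, 800),
                           index=geno.samples.index)
        _, summary = logistic_gwas(geno, status)
        lams.append(summary.gc_lambda)
    assert np.mean(lams) == pytest.approx(1.0, abs=0.05)


def test_planted_risk_snp_detected():
    """OR 1.5 risk SNP, 1000 cases / 1000 controls: detected at p < 1e-4 in
    at least 9 of 10 seeds."""
    hits = 0
    for seed in range(10):
        cfg = small_config(seed=200 + seed, n_cases=1000, n_controls=1000,
                           n_snps=50, n_probes=5, n_chromosomes=1,
                           n_risk_snps=1, risk_or=1.5)
        geno = simulate_genotypes(cfg)
        pheno, _, _, _, truth = simulate_phenotype_and_expression(geno, cfg)
        table, _ = logistic_gwas(geno, pheno["status"])
        p = table.set_index("snp").loc[truth.risk_snps["snp"].iloc[0], "p"]
        hits += p < 1e-4
    assert hits >= 9


def test_separated_snp_is_flagged_not_fatal():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, 100)
    x = y.astype(float) * 2  # perfect separation
    geno = _single_snp_geno(x, y)
    table, summary = logistic_gwas(geno, pd.Series(y, index=geno.samples.index))
    assert not table["converged"].iloc[0]
    assert np.isnan(table["p"].iloc[0])
    assert summary.n_failed == 1


# --------------------------------------------------------------------------- #
# prioritization
# --------------------------------------------------------------------------- #

def test_prioritization_edge_cases_and_oracle():
    pairs = pd.DataFrame({"snp": ["a", "b", "c", "a"],
                          "probe": ["P1", "P2", "P3", "P4"]})
    gwas = pd.DataFrame({"snp": ["a", "b", "c"], "p": [0.01, 0.2, 0.04]})
    all_sel, _ = prioritize_eqtls(pairs, gwas, p_cut=1.0)
    assert len(all_sel) == 4
    none_sel, _ = prioritize_eqtls(pairs, gwas, p_cut=0.0)
    assert len(none_sel) == 0
    sel, snps = prioritize_eqtls(pairs, gwas, p_cut=0.05)
    assert set(zip(sel["snp"], sel["probe"])) == {("a", "P1"), ("c", "P3"), ("a", "P4")}
    assert set(snps) == {"a", "c"}


# --------------------------------------------------------------------------- #
# enrichment
# --------------------------------------------------------------------------- #

def _maf_series(rng, ids):
    return pd.Series(rng.uniform(0.05, 0.5, len(ids)), index=ids)


def test_maximal_enrichment_gives_minimal_p():
    rng = np.random.default_rng(5)
    pos = {f"p{i}" for i in range(50)}
    neg = {f"n{i}" for i in range(2000)}
    maf = _maf_series(rng, sorted(pos | neg))
    out = eqtl_enrichment_test(pos, neg, eqtl_snps=set(pos), maf=maf, n_perm=999, seed=1)
    assert out["observed"] == 50
    assert out["empirical_p"] == pytest.approx(1 / 1000)


def test_enrichment_requires_feasible_bins():
    rng = np.random.default_rng(6)
    pos = {f"p{i}" for i in range(30)}
    neg = {f"n{i}" for i in range(10)}
    maf = _maf_series(rng, sorted(pos | neg))
    with pytest.raises(ValueError, match="bin"):
        eqtl_enrichment_test(pos, neg, set(), maf, n_perm=10, seed=1)


def test_enrichment_calibrated_under_null():
    """eQTL membership independent of the pos/neg split: empirical p is
    (discretely) uniform, rejecting at 0.05 about 5% of the time."""
    rng = np.random.default_rng(7)
    ids = [f"s{i}" for i in range(3000)]
    maf = _maf_series(rng, ids)
    pvals = []
    for run in range(200):
        r = np.random.default_rng(1000 + run)
        perm = r.permutation(ids)
        pos = set(perm[:150])
        neg = set(perm[150:])
        eqtls = set(r.choice(ids, size=300, replace=False))
        out = eqtl_enrichment_test(pos, neg, eqtls, maf, n_perm=499, seed=run)
        pvals.append(out["empirical_p"])
    pvals = np.array(pvals)
    rej = (pvals <= 0.05).mean()
    se = np.sqrt(0.05 * 0.95 / 200)
    assert rej <= 0.05 + 3 * se
    assert 0.35 <= pvals.mean() <= 0.65


# --------------------------------------------------------------------------- #
# replication
# --------------------------------------------------------------------------- #

def test_strong_eqtls_replicate_across_split_halves():
    cfg = small_config(seed=301, n_cases=300, n_controls=300, n_cis_effects=5,
                       cis_beta=1.2, n_probes=50, n_snps=300, n_chromosomes=3)
    bundle, truth = simulate_bundle(cfg)
    ids = bundle.genotypes.samples.index
    half1, half2 = ids[:300], ids[300:]
    covs_all = bundle.phenotypes[["status", "age", "sex", "riluzole"]].astype(float)

    def half(ids_half):
        g = bundle.genotypes.subset_samples(ids_half)
        e = quantile_normalize_log2(bundle.expression.loc[ids_half])
        return g, e, covs_all.loc[ids_half]

    g1, e1, c1 = half(half1)
    pairs, M = enumerate_cis_pairs(g1.snps, bundle.probe_annotation)
    res1 = map_cis_eqtls(g1, e1, c1, pairs)
    call1 = call_significant_eqtls(res1, g1, e1, c1, M, n_perm=50, seed=2)
    planted = set(zip(truth.cis_pairs["snp"], truth.cis_pairs["probe"]))
    sel = call1.significant
    sel_planted = [(s, p) in planted for s, p in zip(sel["snp"], sel["probe"])]
    assert sum(sel_planted) >= 4

    g2, e2, c2 = half(half2)
    replicated, dropped = replicate_eqtls(sel, g2, e2, c2, n_perm=50, seed=3)
    rep_planted = {(s, p) for s, p in zip(replicated["snp"], replicated["probe"])} & planted
    assert len(rep_planted) >= 0.9 * sum(sel_planted)
    assert len(dropped) == 0


def test_empty_selection_replicates_to_empty():
    cfg = small_config(seed=303, n_snps=50, n_probes=10, n_chromosomes=1)
    bundle, _ = simulate_bundle(cfg)
    expr = quantile_normalize_log2(bundle.expression)
    covs = bundle.phenotypes[["status", "age"]].astype(float)
    empty = pd.DataFrame(columns=["snp", "probe", "distance"])
    replicated, dropped = replicate_eqtls(empty, bundle.genotypes, expr, covs, n_perm=20)
    assert len(replicated) == 0 and len(dropped) == 0


# --------------------------------------------------------------------------- #
# clumping
# --------------------------------------------------------------------------- #

def _ld_trio_geno(seed=2, n=500):
    rng = np.random.default_rng(seed)
    a = rng.binomial(2, 0.3, n).astype(float)
    b = a.copy()
    flip = rng.random(n) < 0.18
    b[flip] = rng.binomial(2, 0.3, flip.sum())
    c = rng.binomial(2, 0.3, n).astype(float)
    snps = pd.DataFrame({"chrom": ["1"] * 3, "pos": [100, 200, 300],
                         "a1": ["A"] * 3, "a2": ["G"] * 3},
                        index=pd.Index(["A", "B", "C"], name="snp"))
    samples = pd.DataFrame(index=pd.Index([f"S{i}" for i in range(n)], name="sample"))
    return GenotypeMatrix(np.column_stack([a, b, c]), snps, samples)


def test_greedy_clump_hand_trace():
    geno = _ld_trio_geno()
    assoc = pd.DataFrame({"snp": ["A", "B", "C"], "p": [1e-6, 1e-4, 1e-3]})
    clumps, final = clump_and_correct(assoc, geno, r2_min=0.5)
    assert len(clumps) == 2
    first = clumps[clumps["index_snp"] == "A"].iloc[0]
    assert set(first["members"].split(",")) == {"A", "B"}
    assert clumps["index_p"].tolist() == [1e-6, 1e-3]
    # Bonferroni by the clump count
    np.testing.assert_allclose(clumps["p_bonf"], [2e-6, 2e-3])


def test_independent_snps_form_singleton_clumps():
    cfg = small_config(seed=311, block_size=1, n_snps=100, n_chromosomes=1,
                       snp_spacing=3_000_000)
    geno = simulate_genotypes(cfg, n_samples=400)
    rng = np.random.default_rng(0)
    assoc = pd.DataFrame({"snp": geno.snps.index, "p": rng.uniform(size=100)})
    clumps, _ = clump_and_correct(assoc, geno, r2_min=0.5, window=1_000_000)
    assert len(clumps) == 100
    assert (clumps["n_members"] == 1).all()
    member_union = sum((c.split(",") for c in clumps["members"]), [])
    assert sorted(member_union) == sorted(geno.snps.index)  # partition


def test_clumps_partition_tested_snps(planted_bundle):
    cfg, bundle, _ = planted_bundle
    geno = bundle.genotypes
    rng = np.random.default_rng(5)
    assoc = pd.DataFrame({"snp": geno.snps.index, "p": rng.uniform(size=geno.n_snps)})
    clumps, _ = clump_and_correct(assoc, geno)
    members = sum((c.split(",") for c in clumps["members"]), [])
    assert len(members) == geno.n_snps
    assert set(members) == set(geno.snps.index)
    assert clumps["n_members"].sum() == geno.n_snps


def test_clump_bonferroni_arithmetic_at_study_scale():
    assert bonferroni_correct(1.32e-4, 322) == pytest.approx(0.0425, abs=5e-4)


# --------------------------------------------------------------------------- #
# power
# --------------------------------------------------------------------------- #

def test_required_sample_size_monotone_in_or_and_power():
    base = required_sample_size(PowerQuery(maf=0.3, odds_ratio=1.2))
    bigger_or = required_sample_size(PowerQuery(maf=0.3, odds_ratio=2.0))
    lower_power = required_sample_size(PowerQuery(maf=0.3, odds_ratio=1.2, power=0.5))
    assert bigger_or < base
    assert lower_power < base
    assert bigger_or < 200


def test_or_of_one_is_unattainable():
    with pytest.raises(ValueError, match="OR = 1"):
        required_sample_size(PowerQuery(maf=0.3, odds_ratio=1.0))


def test_required_sample_size_verified_by_monte_carlo():
    q = PowerQuery(maf=0.2, odds_ratio=1.25, alpha=0.05, power=0.8)
    n = required_sample_size(q)
    power = empirical_power(n, q, n_sim=2000, seed=11)
    assert 0.78 <= power <= 0.84


# --------------------------------------------------------------------------- #
# joint two-stage association
# --------------------------------------------------------------------------- #

def test_joint_pooled_strengthens_a_shared_signal():
    from eqtlscreen.gwas import joint_association
    from eqtlscreen.simulate import simulate_genotypes, simulate_phenotype_and_expression

    cfg = small_config(seed=401, n_cases=400, n_controls=400, n_snps=40,
                       n_probes=5, n_chromosomes=1, n_risk_snps=1, risk_or=1.6)
    geno = simulate_genotypes(cfg, n_samples=1600)
    pheno, _, _, _, truth = simulate_phenotype_and_expression(geno, cfg)
    geno.samples["status"] = pheno["status"]
    ids = geno.samples.index
    g1, g2 = geno.subset_samples(ids[:800]), geno.subset_samples(ids[800:])
    t1, _ = logistic_gwas(g1, g1.samples["status"], stage="discovery")
    t2, _ = logistic_gwas(g2, g2.samples["status"], stage="replication")
    pooled = joint_association(g1, g2).set_index("snp")
    meta = joint_association(g1, g2, method="meta",
                             assoc_disc=t1, assoc_rep=t2).set_index("snp")
    risk = truth.risk_snps["snp"].iloc[0]
    p1 = t1.set_index("snp").loc[risk, "p"]
    p2 = t2.set_index("snp").loc[risk, "p"]
    assert pooled.loc[risk, "p"] < min(p1, p2)
    assert meta.loc[risk, "p"] < min(p1, p2)
    # meta beta lies between (or at) the stage estimates
    b1 = t1.set_index("snp").loc[risk, "beta"]
    b2 = t2.set_index("snp").loc[risk, "beta"]
    assert min(b1, b2) - 1e-12 <= meta.loc[risk, "beta"] <= max(b1, b2) + 1e-12
    # pooled and meta agree closely for a common, well-behaved signal
    assert pooled.loc[risk, "beta"] == pytest.approx(meta.loc[risk, "beta"], abs=0.05)
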