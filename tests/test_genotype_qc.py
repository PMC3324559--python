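"""Genotype QC: exact Hardy-Weinberg test against a brute-force enumeration
oracle, the QC cascade on planted defects, LD pruning, method-of-moments
relatedness and structure PCA."""

import math

import numpy as np
import pandas as pd
import pytest

from eqtlscreen.core import GenotypeMatrix
from eqtlscreen.genotype_qc import (
    QcThresholds,
    estimate_relatedness,
    hwe_exact_test,
    ld_prune,
    pca_structure,
    qc_genotypes,
)
from eqtlscreen.simulate import simulate_genotypes

from conftest import small_config


# --------------------------------------------------------------------------- #
# HWE exact test
# --------------------------------------------------------------------------- #

def hwe_enumeration_oracle(naa: int, nab: int, nbb: int) -> float:
    """Independent brute-force enumeration of the conditional heterozygote
    distribution, using exact integer combinatorics."""
    n = naa + nab + nbb
    na = 2 * naa + nab  # count of the 'a' allele
    probs = {}
    for h in range(0, min(na, 2 * n - na) + 1):
        if (na - h) % 2:
            continue
        hom_a = (na - h) // 2
        hom_b = n - h - hom_a
        if hom_a < 0 or hom_b < 0:
            continue
        w = (
            math.factorial(n)
            // (math.factorial(hom_a) * math.factorial(h) * math.factorial(hom_b))
            * 2**h
        )
        probs[h] = w
    total = sum(probs.values())
    p_obs = probs[nab] / total
    return sum(v / total for v in probs.values() if v / total <= p_obs * (1 + 1e-12))


def test_hwe_matches_enumeration_exhaustively():
    """Agreement with full enumeration for every genotype table with n <= 30."""
    for n in range(1, 31):
        for naa in range(n + 1):
            for nab in range(n - naa + 1):
                nbb = n - naa - nab
                expected = hwe_enumeration_oracle(naa, nab, nbb)
                got = hwe_exact_test(naa, nab, nbb)
                assert got == pytest.approx(expected, rel=1e-9), (naa, nab, nbb)


@pytest.mark.parametrize(
    "counts, check",
    [
        ((0, 0, 50), lambda p: p == 1.0),
        ((1, 2, 1), lambda p: p == pytest.approx(hwe_enumeration_oracle(1, 2, 1), rel=1e-9)),
        ((50, 0, 50), lambda p: p < 1e-20),
    ],
)
def test_hwe_reference_points(counts, check):
    assert check(hwe_exact_test(*counts))


def test_hwe_rejects_negative_counts():
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 2, 3)


def test_hwe_type_one_error_is_conservative():
    """On null HWE data the rejection rate at 0.05 stays at or below
    0.05 + 3 binomial SEs (the exact test is conservative)."""
    rng = np.random.default_rng(0)
    m = 2000
    n = 500
    rej = 0
    for _ in range(m):
        p = rng.uniform(0.1, 0.5)
        g = rng.binomial(2, p, size=n)
        if hwe_exact_test(int((g == 2).sum()), int((g == 1).sum()), int((g == 0).sum())) < 0.05:
            rej += 1
    bound = 0.05 + 3 * math.sqrt(0.05 * 0.95 / m)
    assert rej / m <= bound


# --------------------------------------------------------------------------- #
# QC cascade
# --------------------------------------------------------------------------- #

def _planted_defect_geno(seed=0):
    cfg = small_config(seed=seed, n_snps=200, n_chromosomes=2)
    geno = simulate_genotypes(cfg, n_samples=300)
    rng = np.random.default_rng(seed + 1)
    geno.samples["status"] = rng.integers(0, 2, geno.n_samples)
    # plant 10 SNPs at ~90% call rate
    bad = rng.choice(geno.n_snps, size=10, replace=False)
    for j in bad:
        miss = rng.choice(geno.n_samples, size=int(0.1 * geno.n_samples) + 3, replace=False)
        geno.dosage[miss, j] = np.nan
    return geno, set(geno.snps.index[bad])


def test_qc_removes_exactly_planted_low_callrate_snps():
    geno, bad_ids = _planted_defect_geno(seed=41)
    th = QcThresholds(snp_call_rate=0.95, maf_min=0.0, hwe_p_min=0.0,
                      diff_missing_p_min=0.0, het_sd=0.0, sample_call_rate=0.0)
    out, report = qc_genotypes(geno, th)
    assert set(report.removed["snp_call_rate"]) == bad_ids
    assert out.n_snps == geno.n_snps - 10


def test_qc_noop_thresholds_preserve_input():
    geno, _ = _planted_defect_geno(seed=43)
    th = QcThresholds(snp_call_rate=0.0, maf_min=0.0, hwe_p_min=0.0,
                      diff_missing_p_min=0.0, het_sd=0.0, sample_call_rate=0.0)
    out, report = qc_genotypes(geno, th)
    assert out.n_snps == geno.n_snps
    assert out.n_samples == geno.n_samples
    assert all(len(v) == 0 for v in report.removed.values())


def test_qc_counts_are_conserved_and_idempotent():
    """Removal counts reconcile with input/output sizes, and the SNP-level
    cascade is a fixed point of itself.  The heterozygosity criterion is a
    relative (mean +/- k SD) cut, so it is excluded here: recomputing a
    relative threshold on its own output can always trim further."""
    geno, _ = _planted_defect_geno(seed=47)
    th = QcThresholds(het_sd=0.0)
    out, report = qc_genotypes(geno, th)
    n_snp_removed = sum(
        len(report.removed[k])
        for k in ("snp_call_rate", "maf", "hwe_controls", "diff_missingness")
    )
    n_sample_removed = sum(
        len(report.removed[k]) for k in ("sample_call_rate", "heterozygosity")
    )
    assert geno.n_snps - n_snp_removed == out.n_snps
    assert geno.n_samples - n_sample_removed == out.n_samples
    again, report2 = qc_genotypes(out, th)
    assert again.n_snps == out.n_snps
    assert again.n_samples == out.n_samples
    assert all(len(v) == 0 for v in report2.removed.values())


def test_qc_requires_status_labels():
    cfg = small_config(seed=1, n_snps=20)
    geno = simulate_genotypes(cfg, n_samples=20)
    with pytest.raises(ValueError, match="status"):
        qc_genotypes(geno, QcThresholds())


# --------------------------------------------------------------------------- #
# LD pruning
# --------------------------------------------------------------------------- #

def test_prune_keeps_one_of_two_duplicates():
    rng = np.random.default_rng(5)
    g = rng.binomial(2, 0.3, size=200).astype(float)
    other = rng.binomial(2, 0.4, size=200).astype(float)
    dosage = np.column_stack([g, g, other])
    snps = pd.DataFrame({"chrom": ["1"] * 3, "pos": [100, 200, 300],
                         "a1": ["A"] * 3, "a2": ["G"] * 3},
                        index=pd.Index(["dup1", "dup2", "ind"], name="snp"))
    samples = pd.DataFrame(index=pd.Index([f"S{i}" for i in range(200)], name="sample"))
    geno = GenotypeMatrix(dosage, snps, samples)
    kept = ld_prune(geno, window_snps=3, step=1, r2_max=0.5)
    assert len(set(kept) & {"dup1", "dup2"}) == 1
    assert "ind" in set(kept)


def test_prune_retains_independent_snps():
    cfg = small_config(seed=53, block_size=1, n_snps=300, n_chromosomes=3)
    geno = simulate_genotypes(cfg, n_samples=600)
    kept = ld_prune(geno, window_snps=50, step=5, r2_max=0.5)
    assert len(kept) >= 0.97 * geno.n_snps


def test_pruned_set_has_no_high_ld_pair_within_window():
    """Brute-force all-pairs scan over each window of the retained set."""
    cfg = small_config(seed=59, block_size=10, n_founder_haplotypes=6,
                       n_snps=200, n_chromosomes=2)
    geno = simulate_genotypes(cfg, n_samples=400)
    window, r2_max = 20, 0.3
    kept = ld_prune(geno, window_snps=window, step=5, r2_max=r2_max)
    sub = geno.subset_snps(kept)
    X = sub.dosage_filled()
    for chrom in sub.snps["chrom"].unique():
        idx = np.where((sub.snps["chrom"] == chrom).to_numpy())[0]
        for a_pos in range(len(idx)):
            for b_pos in range(a_pos + 1, min(a_pos + window, len(idx))):
                a, b = idx[a_pos], idx[b_pos]
                if X[:, a].std() == 0 or X[:, b].std() == 0:
                    continue
                r2 = np.corrcoef(X[:, a], X[:, b])[0, 1] ** 2
                assert r2 <= r2_max + 1e-9


def test_prune_rejects_tiny_window():
    cfg = small_config(seed=1, n_snps=10)
    geno = simulate_genotypes(cfg, n_samples=20)
    with pytest.raises(ValueError):
        ld_prune(geno, window_snps=1, step=1, r2_max=0.5)


# --------------------------------------------------------------------------- #
# relatedness
# --------------------------------------------------------------------------- #

def _pedigree_genotypes(seed=0, n_snps=1500, n_sib_pairs=12, n_unrelated=24):
    """Founder-based pedigree: sib pairs share parental haplotypes."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.5, size=n_snps)
    rows = []
    for _ in range(n_sib_pairs):
        pat = rng.random((2, n_snps)) < p
        mat = rng.random((2, n_snps)) < p
        for _ in range(2):
            child = pat[rng.integers(0, 2)].astype(float) + mat[rng.integers(0, 2)]
            rows.append(child)
    for _ in range(n_unrelated):
        rows.append((rng.random(n_snps) < p).astype(float) + (rng.random(n_snps) < p))
    dosage = np.array(rows)
    snps = pd.DataFrame({"chrom": "1", "pos": np.arange(1, n_snps + 1) * 1000,
                         "a1": "A", "a2": "G"},
                        index=pd.Index([f"rs{i}" for i in range(n_snps)], name="snp"))
    samples = pd.DataFrame(index=pd.Index([f"S{i:03d}" for i in range(len(rows))], name="sample"))
    return GenotypeMatrix(dosage, snps, samples)


def test_duplicate_sample_has_pihat_near_one():
    geno = _pedigree_genotypes(seed=61)
    dos = geno.dosage.copy()
    dos[1] = dos[0]
    dup = GenotypeMatrix(dos, geno.snps, geno.samples)
    table, removal = estimate_relatedness(dup, pihat_max=0.2)
    pair = table[(table["id1"] == "S000") & (table["id2"] == "S001")]
    assert pair["pi_hat"].iloc[0] >= 0.95
    assert len(removal) >= 1


def test_sibs_and_unrelated_pihat_scale():
    geno = _pedigree_genotypes(seed=67, n_sib_pairs=12, n_unrelated=24)
    table, _ = estimate_relatedness(geno, pihat_max=0.2)
    sib_ids = {(f"S{2*i:03d}", f"S{2*i+1:03d}") for i in range(12)}
    is_sib = [(r.id1, r.id2) in sib_ids for r in table.itertuples()]
    sib = table.loc[is_sib, "pi_hat"]
    unrel = table.loc[[not s and int(r.id1[1:]) >= 24 and int(r.id2[1:]) >= 24
                       for s, r in zip(is_sib, table.itertuples())], "pi_hat"]
    assert sib.mean() == pytest.approx(0.5, abs=0.1)
    assert unrel.mean() == pytest.approx(0.0, abs=0.05)


def test_ibs_counts_sum_to_cocalled():
    geno = _pedigree_genotypes(seed=71, n_snps=200, n_sib_pairs=2, n_unrelated=4)
    geno.dosage[0, :10] = np.nan
    table, _ = estimate_relatedness(geno)
    total = table["ibs0"] + table["ibs1"] + table["ibs2"]
    assert (total == table["n_cocalled"]).all()


# --------------------------------------------------------------------------- #
# PCA structure
# --------------------------------------------------------------------------- #

def test_pc1_separates_drifted_subpopulations():
    cfg = small_config(seed=73, n_snps=2000, n_chromosomes=20, block_size=5,
                       fst=0.1, admix_fraction=0.5)
    geno = simulate_genotypes(cfg, n_samples=300)
    res = pca_structure(geno)
    sub = geno.samples.loc[res.coordinates.index, "subpop"]
    r = np.corrcoef(res.coordinates["PC1"], sub)[0, 1]
    assert abs(r) > 0.9


def test_no_structure_means_no_axis_tracks_labels():
    cfg = small_config(seed=79, n_snps=2000, n_chromosomes=20, fst=0.0,
                       admix_fraction=0.5)
    geno = simulate_genotypes(cfg, n_samples=300)
    res = pca_structure(geno)
    sub = geno.samples.loc[res.coordinates.index, "subpop"]
    for col in res.coordinates.columns:
        assert abs(np.corrcoef(res.coordinates[col], sub)[0, 1]) < 0.3


def test_planted_extreme_samples_are_removed_and_recomputed():
    cfg = small_config(seed=83, n_snps=1000, n_chromosomes=10)
    geno = simulate_genotypes(cfg, n_samples=200)
    dos = geno.dosage.copy()
    dos[0] = 2.0  # homozygous-minor everywhere: far outside the cloud
    dos[1] = 2.0
    geno = GenotypeMatrix(dos, geno.snps, geno.samples)
    res = pca_structure(geno, outlier_sd=6.0)
    assert {"S00000", "S00001"} <= set(res.outliers)
    assert not set(res.outliers) & set(res.coordinates.index)
    assert res.n_iterations >= 2


def test_pca_coordinates_invariant_to_sample_order():
    cfg = small_config(seed=89, n_snps=500, n_chromosomes=5, fst=0.05,
                       admix_fraction=0.4)
    geno = simulate_genotypes(cfg, n_samples=120)
    res1 = pca_structure(geno, n_axes=4)
    rng = np.random.default_rng(0)
    perm = rng.permutation(geno.n_samples)
    res2 = pca_structure(geno.subset_samples(geno.samples.index[perm]), n_axes=4)
    c1 = res1.coordinates.sort_index()
    c2 = res2.coordinates.sort_index()
    for col in c1.columns:
        dot = np.sign(np.dot(c1[col], c2[col]))
        np.testing.assert_allclose(c1[col], dot * c2[col], atol=1e-6)
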