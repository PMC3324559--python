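"""Case-control association, eQTL prioritization/enrichment, replication,
LD clumping with clump-count Bonferroni correction, and power calculation.

Association per SNP is maximum-likelihood logistic regression of status on
additive minor-allele dosage plus covariates (IRLS, tolerance 1e-8, at most
25 iterations), with a Wald test on the dosage coefficient.  Genomic-control
lambda is the median association chi-square divided by 0.4549 (the null
median of a 1-df chi-square).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .core import GenotypeMatrix

_CHI2_NULL_MEDIAN = 0.4549364231195724  # median of chi-square(1)


@dataclass
class GwasRunSummary:
    n_snps_tested: int
    n_failed: int
    gc_lambda: float
    bonferroni_threshold: float
    n_nominal: int  # p < 0.05
    n_bonferroni: int


@dataclass
class PowerQuery:
    maf: float
    odds_ratio: float
    alpha: float = 0.05
    power: float = 0.8

    def validate(self) -> None:
        if not (0 < self.maf <= 0.5):
            raise ValueError("maf must lie in (0, 0.5]")
        if not (0 < self.alpha < 1) or not (0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")


# --------------------------------------------------------------------------- #
# logistic association scan
# --------------------------------------------------------------------------- #

def logistic_gwas(
    geno: GenotypeMatrix,
    status: pd.Series | np.ndarray,
    covs: pd.DataFrame | None = None,
    stage: str = "discovery",
    tol: float = 1e-8,
    max_iter: int = 25,
) -> tuple[pd.DataFrame, GwasRunSummary]:
    """Per-SNP logistic regression scan.

    Non-converged or separated SNPs are flagged with missing p and excluded
    from lambda.  Returns the association table (snp, minor allele, OR, beta,
    se, p, n, converged, stage) and a run summary.
    """
    if isinstance(status, pd.Series):
        status = status.loc[geno.samples.index].to_numpy()
    y = np.asarray(status, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("status must be binary 0/1")
    n = geno.n_samples
    if covs is not None:
        C = np.column_stack([np.ones(n), covs.loc[geno.samples.index].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(C) < C.shape[1]:
            raise ValueError("GWAS covariates are not full rank")
    else:
        C = np.ones((n, 1))

    rows = []
    for j, sid in enumerate(geno.snps.index):
        g = geno.dosage[:, j]
        mask = ~np.isnan(g)
        Xj = np.column_stack([C[mask], g[mask]])
        yj = y[mask]
        beta, se, converged = _irls_logistic(Xj, yj, tol=tol, max_iter=max_iter)
        if converged:
            z = beta / se
            p = 2 * stats.norm.sf(abs(z))
        else:
            p = np.nan
        rows.append(
            {
                "snp": sid,
                "minor_allele": geno.snps.iloc[j]["a1"],
                "or": math.exp(beta) if converged else np.nan,
                "beta": beta if converged else np.nan,
                "se": se if converged else np.nan,
                "p": p,
                "n": int(mask.sum()),
                "converged": converged,
                "stage": stage,
            }
        )
    table = pd.DataFrame(rows)
    ok = table["converged"]
    chi2 = (table.loc[ok, "beta"] / table.loc[ok, "se"]) ** 2
    gc_lambda = float(np.median(chi2) / _CHI2_NULL_MEDIAN) if ok.any() else np.nan
    bonf = 0.05 / max(int(ok.sum()), 1)
    summary = GwasRunSummary(
        n_snps_tested=int(ok.sum()),
        n_failed=int((~ok).sum()),
        gc_lambda=gc_lambda,
        bonferroni_threshold=bonf,
        n_nominal=int((table.loc[ok, "p"] < 0.05).sum()),
        n_bonferroni=int((table.loc[ok, "p"] < bonf).sum()),
    )
    return table, summary


def _irls_logistic(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 25
) -> tuple[float, float, bool]:
    """Newton/IRLS fit; returns (beta_last, se_last, converged) for the last
    column of X (the dosage term)."""
    n, k = X.shape
    if n <= k or X[:, -1].std() < 1e-12:
        return np.nan, np.nan, False
    beta = np.zeros(k)
    ybar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
    beta[0] = math.log(ybar / (1 - ybar))
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        W = mu * (1 - mu)
        if W.max() < 1e-10:
            return np.nan, np.nan, False
        XtW = X.T * W
        H = XtW @ X
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return np.nan, np.nan, False
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            try:
                cov = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                return np.nan, np.nan, False
            se = math.sqrt(max(cov[-1, -1], 0.0))
            if not np.isfinite(se) or se > 100 or abs(beta[-1]) > 30:
                return np.nan, np.nan, False  # quasi-separation
            return float(beta[-1]), se, True
        if np.max(np.abs(beta)) > 50:
            return np.nan, np.nan, False  # divergence / separation
    return np.nan, np.nan, False


def joint_association(
    geno_disc: GenotypeMatrix,
    geno_rep: GenotypeMatrix,
    covs_disc: pd.DataFrame | None = None,
    covs_rep: pd.DataFrame | None = None,
    method: str = "pooled",
    assoc_disc: pd.DataFrame | None = None,
    assoc_rep: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Joint two-stage association on the shared SNP set.

    ``method='pooled'`` concatenates the two cohorts and refits the logistic
    model with a stage-indicator covariate (covariate columns are aligned by
    name, absent columns filled with zero).  ``method='meta'`` combines the
    two per-stage results by fixed-effect inverse-variance weighting and
    needs ``assoc_disc``/``assoc_rep`` instead of a refit.
    """
    if method == "meta":
        if assoc_disc is None or assoc_rep is None:
            raise ValueError("meta method needs the per-stage association tables")
        a = assoc_disc.set_index("snp")
        b = assoc_rep.set_index("snp")
        common = a.index.intersection(b.index)
        wa = 1.0 / a.loc[common, "se"] ** 2
        wb = 1.0 / b.loc[common, "se"] ** 2
        beta = (a.loc[common, "beta"] * wa + b.loc[common, "beta"] * wb) / (wa + wb)
        se = np.sqrt(1.0 / (wa + wb))
        z = beta / se
        return pd.DataFrame(
            {
                "snp": common,
                "beta": beta.to_numpy(),
                "or": np.exp(beta.to_numpy()),
                "se": se.to_numpy(),
                "p": 2 * stats.norm.sf(np.abs(z.to_numpy())),
                "stage": "joint",
            }
        ).reset_index(drop=True)
    if method != "pooled":
        raise ValueError(f"unknown joint method {method!r}")

    common = geno_disc.snps.index.intersection(geno_rep.snps.index)
    g1 = geno_disc.subset_snps(common)
    g2 = geno_rep.subset_snps(common)
    ids = pd.Index(
        [f"d:{i}" for i in g1.samples.index] + [f"r:{i}" for i in g2.samples.index],
        name="sample",
    )
    samples = pd.concat([g1.samples, g2.samples]).set_axis(ids)
    pooled = GenotypeMatrix(np.vstack([g1.dosage, g2.dosage]), g1.snps.copy(), samples)
    c1 = covs_disc if covs_disc is not None else pd.DataFrame(index=g1.samples.index)
    c2 = covs_rep if covs_rep is not None else pd.DataFrame(index=g2.samples.index)
    cols = sorted(set(c1.columns) | set(c2.columns))
    C = pd.DataFrame(0.0, index=ids, columns=cols + ["stage2"])
    n1 = len(c1)
    for col in c1.columns:
        C.iloc[:n1, C.columns.get_loc(col)] = c1[col].to_numpy()
    for col in c2.columns:
        C.iloc[n1:, C.columns.get_loc(col)] = c2[col].to_numpy()
    C.iloc[n1:, C.columns.get_loc("stage2")] = 1.0
    # drop columns that are constant in the pooled design
    C = C.loc[:, C.std() > 0]
    table, _ = logistic_gwas(pooled, samples["status"], C if C.shape[1] else None, stage="joint")
    return table


# --------------------------------------------------------------------------- #
# prioritization and enrichment
# --------------------------------------------------------------------------- #

def prioritize_eqtls(
    eqtl_pairs: pd.DataFrame, gwas: pd.DataFrame, p_cut: float = 0.05
) -> tuple[pd.DataFrame, pd.Index]:
    """Keep significant eQTL pairs whose SNP is nominally disease-associated
    (discovery GWAS p < ``p_cut``).  Returns (pairs, distinct SNP ids)."""
    pmap = gwas.set_index("snp")["p"]
    gp = eqtl_pairs["snp"].map(pmap)
    selected = eqtl_pairs.loc[gp.notna() & (gp < p_cut)].copy()
    selected["gwas_p"] = gp[selected.index]
    return selected, pd.Index(pd.unique(selected["snp"]))


def eqtl_enrichment_test(
    snps_pos: set,
    snps_neg: set,
    eqtl_snps: set,
    maf: pd.Series,
    bin_width: float = 0.05,
    n_perm: int = 100_000,
    seed: int = 0,
) -> dict:
    """MAF-matched permutation test for eQTL enrichment among associated SNPs.

    The observed statistic is the number of eQTL SNPs among ``snps_pos``.
    Each permutation draws, from ``snps_neg`` without replacement, a set
    matching the positive set's per-MAF-bin counts and counts its eQTL
    members; within a bin that count is hypergeometric, so the draws are
    generated bin-wise from the hypergeometric distribution (identical in
    law, and fast).  Empirical p uses the add-one estimator
    ``(1 + #{perm >= obs}) / (1 + n_perm)``.
    """
    if snps_pos & snps_neg:
        raise ValueError("positive and negative SNP sets must be disjoint")
    missing = (snps_pos | snps_neg) - set(maf.index)
    if missing:
        raise ValueError(f"MAF missing for {sorted(missing)[:5]}")
    rng = np.random.default_rng([seed, 43])

    def _bin(ids: set) -> pd.Series:
        b = np.floor(maf.loc[sorted(ids)] / bin_width).astype(int)
        return b.clip(upper=int(0.5 / bin_width) - 1)

    pos_bins = _bin(snps_pos)
    neg_bins = _bin(snps_neg)
    observed = len(snps_pos & eqtl_snps)

    perm_counts = np.zeros(n_perm, dtype=np.int64)
    expected = 0.0
    for b, need in pos_bins.value_counts().items():
        in_bin = neg_bins.index[neg_bins == b]
        n_bin = len(in_bin)
        if need > n_bin:
            raise ValueError(
                f"MAF bin [{b * bin_width:.2f}, {(b + 1) * bin_width:.2f}): "
                f"need {need} matched SNPs, only {n_bin} available"
            )
        k_eqtl = len(set(in_bin) & eqtl_snps)
        perm_counts += rng.hypergeometric(k_eqtl, n_bin - k_eqtl, need, size=n_perm)
        expected += need * k_eqtl / n_bin
    p = (1 + int((perm_counts >= observed).sum())) / (1 + n_perm)
    return {
        "observed": observed,
        "expected": expected,
        "empirical_p": p,
        "n_perm": n_perm,
    }


# --------------------------------------------------------------------------- #
# replication
# --------------------------------------------------------------------------- #

def replicate_eqtls(
    selected_pairs: pd.DataFrame,
    geno: GenotypeMatrix,
    expr: pd.DataFrame,
    covs: pd.DataFrame,
    fdr: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Refit the selected pairs in the replication dataset and call
    significance at ``fdr`` by the permutation-anchored caller restricted to
    the selected pair count.  Pairs whose SNP or probe is absent are dropped
    with a reason.  Returns (replicated pairs, dropped pairs)."""
    from .eqtl import call_significant_eqtls, map_cis_eqtls

    if len(selected_pairs) == 0:
        empty = selected_pairs.copy()
        return empty, pd.DataFrame(columns=["snp", "probe", "reason"])
    have_snp = selected_pairs["snp"].isin(geno.snps.index)
    have_probe = selected_pairs["probe"].isin(expr.columns)
    dropped = selected_pairs.loc[~(have_snp & have_probe), ["snp", "probe"]].copy()
    dropped["reason"] = np.where(
        ~have_snp[dropped.index], "snp_absent", "probe_absent"
    )
    pairs = selected_pairs.loc[have_snp & have_probe, ["snp", "probe"]].copy()
    if "distance" in selected_pairs.columns:
        pairs["distance"] = selected_pairs.loc[pairs.index, "distance"]
    else:
        pairs["distance"] = 0
    res = map_cis_eqtls(geno, expr, covs, pairs)
    call = call_significant_eqtls(
        res, geno, expr, covs, M=len(pairs), n_perm=n_perm, fdr=fdr, seed=seed
    )
    return call.significant, dropped


# --------------------------------------------------------------------------- #
# clumping and final correction
# --------------------------------------------------------------------------- #

def clump_and_correct(
    assoc: pd.DataFrame,
    geno: GenotypeMatrix,
    r2_min: float = 0.5,
    window: int = 1_000_000,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Greedy LD clumping of association results and clump-count Bonferroni.

    Repeatedly the unassigned SNP with the smallest p (ties broken by
    (chromosome, position)) becomes an index; every unassigned SNP within
    ``window`` bp on the same chromosome with dosage r² > ``r2_min`` joins
    its clump.  Each index p is Bonferroni-corrected by the number of clumps;
    clumps with corrected p < ``alpha`` are the final loci.
    """
    tested = assoc.dropna(subset=["p"]).copy()
    snp_ids = [s for s in tested["snp"] if s in geno.snps.index]
    tested = tested[tested["snp"].isin(snp_ids)]
    if len(tested) == 0:
        return pd.DataFrame(columns=["clump", "index_snp", "members", "index_p", "p_bonf"]), pd.DataFrame()
    sub = geno.subset_snps(pd.Index(pd.unique(tested["snp"])))
    X = sub.dosage_filled()
    Xc = X - X.mean(axis=0)
    norms = np.sqrt((Xc**2).sum(axis=0))
    norms[norms == 0] = np.nan
    pos = sub.snps["pos"].to_numpy()
    chrom = sub.snps["chrom"].to_numpy().astype(str)
    idx_of = {s: i for i, s in enumerate(sub.snps.index)}

    tested = tested.assign(
        _chrom=[chrom[idx_of[s]] for s in tested["snp"]],
        _pos=[pos[idx_of[s]] for s in tested["snp"]],
    ).sort_values(["p", "_chrom", "_pos"], kind="mergesort")

    assigned: dict[str, int] = {}
    clumps: list[dict] = []
    for _, row in tested.iterrows():
        s = row["snp"]
        if s in assigned:
            continue
        ci = len(clumps)
        i = idx_of[s]
        members = [s]
        assigned[s] = ci
        cand = [
            t
            for t in tested["snp"]
            if t not in assigned
            and chrom[idx_of[t]] == chrom[i]
            and abs(pos[idx_of[t]] - pos[i]) <= window
        ]
        if cand:
            js = np.array([idx_of[t] for t in cand])
            with np.errstate(invalid="ignore"):
                r = (Xc[:, js].T @ Xc[:, i]) / (norms[js] * norms[i])
            for t, rv in zip(cand, r):
                if np.isfinite(rv) and rv**2 > r2_min:
                    members.append(t)
                    assigned[t] = ci
        clumps.append({"clump": ci, "index_snp": s, "members": members, "index_p": row["p"]})

    n_clumps = len(clumps)
    table = pd.DataFrame(
        [
            {
                "clump": c["clump"],
                "index_snp": c["index_snp"],
                "n_members": len(c["members"]),
                "members": ",".join(c["members"]),
                "index_p": c["index_p"],
                "p_bonf": bonferroni_correct(c["index_p"], n_clumps),
            }
            for c in clumps
        ]
    )
    final = table[table["p_bonf"] < alpha].copy()
    return table, final


def bonferroni_correct(p: float, n_tests: int) -> float:
    """min(1, p * n_tests) — the clump-count correction of an index p."""
    return min(1.0, float(p) * int(n_tests))


# --------------------------------------------------------------------------- #
# power / required sample size
# --------------------------------------------------------------------------- #

def required_sample_size(q: PowerQuery) -> int:
    """Minimum cases (= controls) for a two-proportion chi-square test on
    allele counts, without continuity correction.

    Control allele frequency p0 = maf; case frequency
    p1 = OR p0 / (1 + p0 (OR - 1)).  The required allele count per group is
    ``(z_{1-a/2} sqrt(2 pbar qbar) + z_{power} sqrt(p0 q0 + p1 q1))^2 /
    (p1 - p0)^2`` and persons = ceil(alleles / 2).
    """
    q.validate()
    p0 = q.maf
    if q.odds_ratio == 1.0:
        raise ValueError("OR = 1: no effect to detect; required n is unbounded")
    p1 = q.odds_ratio * p0 / (1 + p0 * (q.odds_ratio - 1))
    pbar = (p0 + p1) / 2
    za = stats.norm.ppf(1 - q.alpha / 2)
    zb = stats.norm.ppf(q.power)
    num = (za * math.sqrt(2 * pbar * (1 - pbar)) + zb * math.sqrt(p0 * (1 - p0) + p1 * (1 - p1))) ** 2
    n_alleles = num / (p1 - p0) ** 2
    return int(math.ceil(n_alleles / 2))


def empirical_power(
    n_per_group: int,
    q: PowerQuery,
    n_sim: int = 2000,
    seed: int = 0,
) -> float:
    """Monte-Carlo check of :func:`required_sample_size`: simulate allele
    counts in ``n_sim`` case-control studies of ``n_per_group`` persons per
    arm and report the rejection rate of the allelic chi-square test."""
    rng = np.random.default_rng([seed, 47])
    p0 = q.maf
    p1 = q.odds_ratio * p0 / (1 + p0 * (q.odds_ratio - 1))
    m = 2 * n_per_group  # alleles per group
    a = rng.binomial(m, p1, size=n_sim).astype(float)  # case minor alleles
    c = rng.binomial(m, p0, size=n_sim).astype(float)
    b, d = m - a, m - c
    n = 2.0 * m
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    crit = stats.chi2.ppf(1 - q.alpha, df=1)
    return float(np.mean(chi2 > crit))
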