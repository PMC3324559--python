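"""cis-eQTL enumeration, per-pair additive linear models, and significance
calling by permutation-anchored false discovery rate.

A cis pair is a SNP within ``half_window`` bp (default 500 kb, i.e. a 1 Mb
window) of a probe's genomic midpoint, on the same chromosome, and not on the
pair-exclusion list.  Each pair is fit by OLS of probe expression on
minor-allele dosage plus the eQTL covariates; missing dosages are handled
per-pair complete-case.

The null for FDR calling permutes the sample-to-genotype-vector assignment:
every subject receives another random subject's genotype vector while the
expression matrix, status and covariates stay with the subject.  This
preserves the LD structure among SNPs and the correlation structure among
probes, so the permutation p-values form an honest null for the whole family
of correlated tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix


# --------------------------------------------------------------------------- #
# enumeration
# --------------------------------------------------------------------------- #

def enumerate_cis_pairs(
    snps: pd.DataFrame,
    probes: pd.DataFrame,
    half_window: int = 500_000,
    exclusions: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, int]:
    """All same-chromosome (snp, probe) pairs with |pos - midpoint| <=
    ``half_window`` (inclusive boundary), minus exclusions.  Returns the pair
    table and the testable count M used as the FDR denominator.
    """
    excluded: set[tuple[str, str]] = set()
    if exclusions is not None and len(exclusions):
        excluded = set(zip(exclusions["snp"], exclusions["probe"]))

    out_snp, out_probe, out_dist = [], [], []
    for chrom in probes["chrom"].astype(str).unique():
        s_mask = snps["chrom"].astype(str) == chrom
        p_mask = probes["chrom"].astype(str) == chrom
        if not s_mask.any() or not p_mask.any():
            continue
        s_ids = snps.index[s_mask].to_numpy()
        s_pos = snps.loc[s_mask, "pos"].to_numpy()
        order = np.argsort(s_pos, kind="mergesort")
        s_ids, s_pos = s_ids[order], s_pos[order]
        for probe, mid in zip(probes.index[p_mask], probes.loc[p_mask, "midpoint"].to_numpy()):
            lo = np.searchsorted(s_pos, mid - half_window, side="left")
            hi = np.searchsorted(s_pos, mid + half_window, side="right")
            for k in range(lo, hi):
                if (s_ids[k], probe) in excluded:
                    continue
                out_snp.append(s_ids[k])
                out_probe.append(probe)
                out_dist.append(int(abs(s_pos[k] - mid)))
    pairs = pd.DataFrame({"snp": out_snp, "probe": out_probe, "distance": out_dist})
    return pairs, len(pairs)


# --------------------------------------------------------------------------- #
# per-pair models
# --------------------------------------------------------------------------- #

def map_cis_eqtls(
    geno: GenotypeMatrix,
    expr: pd.DataFrame,
    covs: pd.DataFrame,
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """OLS of expression on dosage + covariates for every cis pair.

    Returns one row per pair: beta (log2 expression change per minor allele),
    se, t, p, model_r2 (full-model R^2 against the raw probe variance),
    direction = sign(beta), n (samples used), and a skip reason for
    degenerate pairs (constant dosage or too few complete cases).
    """
    samples = expr.index
    if not samples.equals(geno.samples.index) or not samples.equals(covs.index):
        common = geno.samples.index.intersection(expr.index).intersection(covs.index)
        if len(common) == 0:
            raise ValueError("no common samples across genotypes/expression/covariates")
        geno = geno.subset_samples(common)
        expr = expr.loc[common]
        covs = covs.loc[common]
        samples = common
    n = len(samples)
    C = np.column_stack([np.ones(n), covs.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("eQTL covariates are not full rank")
    Q, _ = np.linalg.qr(C)
    p_cov = C.shape[1]

    snp_pos = geno.snps.index.get_indexer(pairs["snp"])
    probe_pos = expr.columns.get_indexer(pairs["probe"])
    if (snp_pos < 0).any() or (probe_pos < 0).any():
        raise KeyError("pair references SNP or probe absent from the data")

    Y = expr.to_numpy(dtype=float)
    G = geno.dosage
    has_missing = np.isnan(G).any(axis=0)

    Yr = Y - Q @ (Q.T @ Y)
    Gf = np.where(np.isnan(G), np.nan, G)
    Gc = geno.dosage_filled()
    Gr = Gc - Q @ (Q.T @ Gc)

    y_tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    yr_ss = (Yr**2).sum(axis=0)

    rows = []
    for (si, pi), (snp, probe, dist) in zip(
        zip(snp_pos, probe_pos), pairs[["snp", "probe", "distance"]].itertuples(index=False)
    ):
        if not has_missing[si]:
            g = Gr[:, si]
            gg = float(g @ g)
            if gg < 1e-12:
                rows.append(_skip_row(snp, probe, dist, n, "constant_dosage"))
                continue
            gy = float(g @ Yr[:, pi])
            beta = gy / gg
            df = n - p_cov - 1
            rss = float(yr_ss[pi]) - beta * gy
            se = np.sqrt(max(rss, 0.0) / max(df, 1) / gg)
            t = beta / se if se > 0 else 0.0
            p = 2 * stats.t.sf(abs(t), df)
            r2 = 1.0 - max(rss, 0.0) / y_tss[pi] if y_tss[pi] > 0 else 0.0
            rows.append(_fit_row(snp, probe, dist, n, beta, se, t, p, r2))
        else:
            mask = ~np.isnan(Gf[:, si])
            n_use = int(mask.sum())
            if n_use <= p_cov + 1:
                rows.append(_skip_row(snp, probe, dist, n_use, "too_few_samples"))
                continue
            g = Gf[mask, si]
            if g.std() < 1e-12:
                rows.append(_skip_row(snp, probe, dist, n_use, "constant_dosage"))
                continue
            X = np.column_stack([C[mask], g])
            y = Y[mask, pi]
            beta_hat, rss_arr, rank, _ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta_hat
            rss = float(resid @ resid)
            df = n_use - X.shape[1]
            XtX_inv = np.linalg.pinv(X.T @ X)
            se = np.sqrt(rss / max(df, 1) * XtX_inv[-1, -1])
            beta = float(beta_hat[-1])
            t = beta / se if se > 0 else 0.0
            p = 2 * stats.t.sf(abs(t), df)
            tss = float(((y - y.mean()) ** 2).sum())
            r2 = 1.0 - rss / tss if tss > 0 else 0.0
            rows.append(_fit_row(snp, probe, dist, n_use, beta, se, t, p, r2))
    return pd.DataFrame(rows)


def _fit_row(snp, probe, dist, n, beta, se, t, p, r2) -> dict:
    return {
        "snp": snp,
        "probe": probe,
        "distance": dist,
        "n": n,
        "beta": beta,
        "se": se,
        "t": t,
        "p": min(max(p, np.nextafter(0, 1)), 1.0),
        "model_r2": float(np.clip(r2, 0.0, 1.0)),
        "direction": int(np.sign(beta)),
        "skip_reason": "",
    }


def _skip_row(snp, probe, dist, n, reason) -> dict:
    return {
        "snp": snp,
        "probe": probe,
        "distance": dist,
        "n": n,
        "beta": np.nan,
        "se": np.nan,
        "t": np.nan,
        "p": np.nan,
        "model_r2": np.nan,
        "direction": 0,
        "skip_reason": reason,
    }


# --------------------------------------------------------------------------- #
# permutation-anchored FDR
# --------------------------------------------------------------------------- #

@dataclass
class EqtlCallResult:
    results: pd.DataFrame  # input results + q (BH over M) + significant flag
    significant: pd.DataFrame
    p_threshold: float
    n_perm: int
    M: int


def call_significant_eqtls(
    results: pd.DataFrame,
    geno: GenotypeMatrix,
    expr: pd.DataFrame,
    covs: pd.DataFrame,
    M: int,
    n_perm: int = 10_000,
    fdr: float = 0.05,
    seed: int = 0,
) -> EqtlCallResult:
    """Call significant pairs by empirical FDR against genotype permutations.

    The permutation null reassigns whole genotype vectors to random subjects
    (expression and covariates fixed); per permutation all pair p-values are
    recomputed.  The empirical FDR at a candidate threshold t is the mean
    permutation count of p <= t divided by the observed count, and the
    significance threshold is the largest observed p with empirical FDR <=
    ``fdr``.  Benjamini-Hochberg q-values against the ``M`` testable
    combinations are reported alongside.
    """
    if n_perm < 10:
        raise ValueError("n_perm < 10: permutation null too coarse")
    rng = np.random.default_rng([seed, 41])

    tested = results[results["skip_reason"] == ""].copy()
    out = results.copy()
    out["q"] = np.nan
    out["significant"] = False
    if len(tested) == 0:
        return EqtlCallResult(out, tested, 0.0, n_perm, M)

    samples = expr.index
    geno = geno.subset_samples(samples)
    covs = covs.loc[samples]
    n = len(samples)
    C = np.column_stack([np.ones(n), covs.to_numpy(dtype=float)])
    Q, _ = np.linalg.qr(C)
    df = n - C.shape[1] - 1

    snp_idx = geno.snps.index.get_indexer(tested["snp"])
    probe_idx = expr.columns.get_indexer(tested["probe"])
    uniq_snps, snp_inv = np.unique(snp_idx, return_inverse=True)
    uniq_probes, probe_inv = np.unique(probe_idx, return_inverse=True)

    Y = expr.to_numpy(dtype=float)[:, uniq_probes]
    Yr = Y - Q @ (Q.T @ Y)
    yr_ss = (Yr**2).sum(axis=0)
    G = geno.dosage_filled()[:, uniq_snps]

    obs_p = tested["p"].to_numpy()
    perm_p_sorted = np.empty(n_perm * len(tested))
    for b in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[perm]
        Gpr = Gp - Q @ (Q.T @ Gp)
        gg = (Gpr**2).sum(axis=0)
        gg[gg < 1e-12] = np.nan
        gy = np.einsum("ij,ij->j", Gpr[:, snp_inv], Yr[:, probe_inv])
        beta = gy / gg[snp_inv]
        rss = yr_ss[probe_inv] - beta * gy
        se = np.sqrt(np.maximum(rss, 0.0) / max(df, 1) / gg[snp_inv])
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = beta / se
        pvals = 2 * stats.t.sf(np.abs(tstat), df)
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        perm_p_sorted[b * len(tested) : (b + 1) * len(tested)] = pvals
    perm_p_sorted.sort()

    order = np.argsort(obs_p, kind="mergesort")
    sorted_obs = obs_p[order]
    # add-one smoothing: a permutation count of zero still contributes 1/n_perm,
    # so the empirical FDR never collapses to exactly zero and the significant
    # set empties as fdr -> 0
    perm_counts = (np.searchsorted(perm_p_sorted, sorted_obs, side="right") + 1) / n_perm
    ranks = np.arange(1, len(sorted_obs) + 1)
    efdr = perm_counts / ranks
    ok = np.where(efdr <= fdr)[0]
    if ok.size:
        p_threshold = float(sorted_obs[ok.max()])
    else:
        p_threshold = 0.0

    sig_mask = obs_p <= p_threshold if p_threshold > 0 else np.zeros(len(tested), bool)
    tested["significant"] = sig_mask
    tested["q"] = bh_qvalues(obs_p, M)
    out.loc[tested.index, "q"] = tested["q"]
    out.loc[tested.index, "significant"] = tested["significant"]
    return EqtlCallResult(
        results=out,
        significant=tested[tested["significant"]].copy(),
        p_threshold=p_threshold,
        n_perm=n_perm,
        M=M,
    )


def bh_qvalues(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg q-values; ``m`` overrides the test count (the
    number of possible cis combinations when not all were computed)."""
    p = np.asarray(p, dtype=float)
    if m is None:
        m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, len(p) + 1)
    q_sorted = p[order] * m / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# --------------------------------------------------------------------------- #
# locus fine-mapping
# --------------------------------------------------------------------------- #

def finemap_locus(
    locus_spec: dict,
    geno: GenotypeMatrix,
    expr: pd.DataFrame,
    covs: pd.DataFrame,
    annot: pd.DataFrame,
    exclusions: pd.DataFrame | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Fit and FDR-correct all cis pairs of one locus.

    ``locus_spec`` is either SNP-anchored — ``{"index_snp": id, "max_dist":
    bp}``, pairing the index SNP with every probe whose midpoint lies within
    ``max_dist`` (strict) — or region-anchored — ``{"chrom", "start",
    "end"}``, taking every cis pair of every SNP inside the interval.
    Benjamini-Hochberg at ``fdr`` over the locus pair count.
    """
    excluded: set[tuple[str, str]] = set()
    if exclusions is not None and len(exclusions):
        excluded = set(zip(exclusions["snp"], exclusions["probe"]))

    records = []
    if "index_snp" in locus_spec:
        sid = locus_spec["index_snp"]
        max_dist = int(locus_spec.get("max_dist", 500_000))
        srow = geno.snps.loc[sid]
        on = annot[annot["chrom"].astype(str) == str(srow["chrom"])]
        for probe, mid in zip(on.index, on["midpoint"]):
            d = abs(int(srow["pos"]) - int(mid))
            if d < max_dist and (sid, probe) not in excluded:
                records.append({"snp": sid, "probe": probe, "distance": d})
    else:
        chrom = str(locus_spec["chrom"])
        lo, hi = int(locus_spec["start"]), int(locus_spec["end"])
        half = int(locus_spec.get("half_window", 500_000))
        in_region = geno.snps[
            (geno.snps["chrom"].astype(str) == chrom)
            & (geno.snps["pos"] >= lo)
            & (geno.snps["pos"] <= hi)
        ]
        pairs, _ = enumerate_cis_pairs(in_region, annot, half_window=half, exclusions=exclusions)
        records = pairs.to_dict("records")

    pairs = pd.DataFrame(records, columns=["snp", "probe", "distance"])
    if len(pairs) == 0:
        return pd.DataFrame(
            columns=["snp", "probe", "distance", "n", "beta", "se", "t", "p",
                     "model_r2", "direction", "skip_reason", "q_locus", "significant"]
        )
    res = map_cis_eqtls(geno, expr, covs, pairs)
    tested = res["skip_reason"] == ""
    res["q_locus"] = np.nan
    res.loc[tested, "q_locus"] = bh_qvalues(res.loc[tested, "p"].to_numpy(), int(tested.sum()))
    res["significant"] = res["q_locus"] <= fdr
    return res
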