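"""SNP- and sample-level genotype quality control.

Implements the standard case-control QC cascade (call rates, MAF, exact
Hardy-Weinberg in controls, differential missingness, heterozygosity
outliers), greedy sliding-window LD pruning, PLINK-style method-of-moments
relatedness (pi-hat), and iterative outlier-removing genotype PCA for
population structure.

r-squared everywhere is the squared Pearson correlation of dosages
(composite LD on unphased genotypes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .core import GenotypeMatrix

__all__ = [
    "QcThresholds",
    "QcReport",
    "hwe_exact_test",
    "qc_genotypes",
    "ld_prune",
    "estimate_relatedness",
    "pca_structure",
    "PcaResult",
]


@dataclass
class QcThresholds:
    snp_call_rate: float = 0.95
    maf_min: float = 0.05
    hwe_p_min: float = 1e-4
    diff_missing_p_min: float = 1e-4
    het_sd: float = 3.0
    sample_call_rate: float = 0.95
    pihat_max: float = 0.2


@dataclass
class QcReport:
    """Removal counts and ids per criterion, in application order."""

    removed: dict[str, list] = field(default_factory=dict)

    def count(self, criterion: str) -> int:
        return len(self.removed.get(criterion, []))

    def total_snps_removed(self) -> int:
        return sum(
            len(v)
            for k, v in self.removed.items()
            if k in ("snp_call_rate", "maf", "hwe_controls", "diff_missingness")
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"criterion": k, "count": len(v), "ids": ",".join(map(str, v))}
                for k, v in self.removed.items()
            ]
        )


# --------------------------------------------------------------------------- #
# Hardy-Weinberg exact test
# --------------------------------------------------------------------------- #

def hwe_exact_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Sums the probabilities of all heterozygote counts (given the observed
    allele counts) that are no more probable than the observed one, under the
    exact conditional distribution
    ``P(n_het | n, n_minor) = n! / (n_hom_minor! n_het! n_hom_major!) *
    2**n_het * n_minor! n_major! / (2n)!``.
    """
    if min(n_hom_minor, n_het, n_hom_major) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_minor + n_het + n_hom_major
    if n == 0:
        raise ValueError("no genotypes")
    n_minor = 2 * n_hom_minor + n_het
    if n_minor > n:  # ensure we count the rarer allele
        n_minor = 2 * n - n_minor
    if n_minor == 0:
        return 1.0
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hets = hets[(n_minor - hets) % 2 == 0]
    hom_rare = (n_minor - hets) // 2
    hom_common = n - hets - hom_rare
    hets = hets[hom_common >= 0]
    hom_rare = hom_rare[hom_common >= 0]
    hom_common = hom_common[hom_common >= 0]
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + hets * np.log(2.0)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = np.where(hets == n_het)[0]
    if obs.size == 0:
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    p_obs = probs[obs[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_pvalues(geno: GenotypeMatrix, sample_mask: np.ndarray | None = None) -> np.ndarray:
    dos = geno.dosage if sample_mask is None else geno.dosage[sample_mask]
    p = np.ones(geno.n_snps)
    for j in range(geno.n_snps):
        col = dos[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        p[j] = hwe_exact_test(int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum()))
    return p


# --------------------------------------------------------------------------- #
# QC cascade
# --------------------------------------------------------------------------- #

def qc_genotypes(
    geno: GenotypeMatrix, th: QcThresholds | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the QC cascade in fixed order and report per-criterion removals.

    Order: sample call rate; SNP call rate; MAF; control-HWE; case/control
    differential missingness (chi-square on called/missing x status);
    per-sample heterozygosity beyond ``het_sd`` SDs of the mean.
    """
    th = th or QcThresholds()
    if "status" not in geno.samples.columns:
        raise ValueError("sample status labels required for QC")
    report = QcReport()
    g = geno

    # 1. sample call rate
    cr = g.sample_call_rate()
    bad = g.samples.index[cr < th.sample_call_rate]
    report.removed["sample_call_rate"] = list(bad)
    g = g.drop_samples(bad)
    if g.n_samples == 0:
        raise RuntimeError("QC removed all samples at criterion 'sample_call_rate'")

    # 2. SNP call rate
    cr = g.snp_call_rate()
    bad = g.snps.index[cr < th.snp_call_rate]
    report.removed["snp_call_rate"] = list(bad)
    g = g.subset_snps(g.snps.index.difference(bad, sort=False))

    # 3. MAF
    maf = g.maf()
    bad = g.snps.index[np.isnan(maf) | (maf < th.maf_min)]
    report.removed["maf"] = list(bad)
    g = g.subset_snps(g.snps.index.difference(bad, sort=False))

    # 4. HWE in controls
    status = g.samples["status"].to_numpy()
    controls = status == 0
    if controls.any() and th.hwe_p_min > 0:
        p = hwe_pvalues(g, controls)
        bad = g.snps.index[p < th.hwe_p_min]
    else:
        bad = g.snps.index[:0]
    report.removed["hwe_controls"] = list(bad)
    g = g.subset_snps(g.snps.index.difference(bad, sort=False))

    # 5. differential missingness (cases vs controls)
    status = g.samples["status"].to_numpy()
    if th.diff_missing_p_min > 0 and (status == 1).any() and (status == 0).any():
        p = _diff_missing_pvalues(g.dosage, status)
        bad = g.snps.index[p < th.diff_missing_p_min]
    else:
        bad = g.snps.index[:0]
    report.removed["diff_missingness"] = list(bad)
    g = g.subset_snps(g.snps.index.difference(bad, sort=False))

    # 6. heterozygosity outliers
    if th.het_sd > 0 and g.n_snps > 0:
        het = np.nanmean(g.dosage == 1, axis=1)
        mu, sd = het.mean(), het.std()
        bad = g.samples.index[np.abs(het - mu) > th.het_sd * sd] if sd > 0 else g.samples.index[:0]
    else:
        bad = g.samples.index[:0]
    report.removed["heterozygosity"] = list(bad)
    g = g.drop_samples(bad)
    if g.n_samples == 0:
        raise RuntimeError("QC removed all samples at criterion 'heterozygosity'")
    return g, report


def _diff_missing_pvalues(dosage: np.ndarray, status: np.ndarray) -> np.ndarray:
    miss = np.isnan(dosage)
    n_case = int((status == 1).sum())
    n_ctrl = int((status == 0).sum())
    a = miss[status == 1].sum(axis=0)  # missing in cases
    b = n_case - a
    c = miss[status == 0].sum(axis=0)
    d = n_ctrl - c
    n = n_case + n_ctrl
    # Pearson chi-square on the 2x2 table, df=1, no continuity correction
    with np.errstate(divide="ignore", invalid="ignore"):
        num = n * (a * d - b * c) ** 2
        den = (a + b) * (c + d) * (a + c) * (b + d)
        chi2 = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    return stats.chi2.sf(chi2, df=1)


# --------------------------------------------------------------------------- #
# LD pruning
# --------------------------------------------------------------------------- #

def ld_prune(
    geno: GenotypeMatrix, window_snps: int = 50, step: int = 5, r2_max: float = 0.2
) -> pd.Index:
    """Greedy sliding-window pruning to approximate linkage equilibrium.

    Within each window, while any retained pair exceeds ``r2_max``, the
    member with the lower MAF is dropped (tie: the later position).  Windows
    never span chromosomes.  Returns the retained SNP ids.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    X = geno.dosage_filled()
    maf = geno.maf()
    pos = geno.snps["pos"].to_numpy()
    keep = np.ones(geno.n_snps, dtype=bool)
    for chrom in geno.snps["chrom"].unique():
        idx = np.where((geno.snps["chrom"] == chrom).to_numpy())[0]
        idx = idx[np.argsort(pos[idx], kind="mergesort")]
        startpos = 0
        while startpos < len(idx):
            window = idx[startpos : startpos + window_snps]
            _prune_window(X, maf, pos, window, keep, r2_max)
            if startpos + window_snps >= len(idx):
                break
            startpos += step
    return geno.snps.index[keep]


def _prune_window(X, maf, pos, window, keep, r2_max) -> None:
    active = [i for i in window if keep[i]]
    while len(active) > 1:
        G = X[:, active]
        sd = G.std(axis=0)
        ok = sd > 0
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(G[:, ok].T) if ok.sum() > 1 else np.zeros((1, 1))
        r2 = np.nan_to_num(r**2)
        np.fill_diagonal(r2, 0.0)
        if r2.size == 0 or r2.max() <= r2_max:
            return
        i_loc, j_loc = np.unravel_index(np.argmax(r2), r2.shape)
        ok_idx = [a for a, flag in zip(active, ok) if flag]
        a, b = ok_idx[i_loc], ok_idx[j_loc]
        if maf[a] < maf[b] or (maf[a] == maf[b] and pos[a] > pos[b]):
            drop = a
        else:
            drop = b
        keep[drop] = False
        active.remove(drop)


# --------------------------------------------------------------------------- #
# relatedness
# --------------------------------------------------------------------------- #

def estimate_relatedness(
    geno: GenotypeMatrix, pihat_max: float = 0.2
) -> tuple[pd.DataFrame, list]:
    """Method-of-moments IBD from IBS counts and allele frequencies.

    For each pair: P(IBD=0) from observed IBS0 against its expectation under
    no sharing, P(IBD=1) from the IBS1 excess, P(IBD=2) as remainder;
    ``pi_hat = P(IBD=1)/2 + P(IBD=2)`` truncated to [0, 1].  Returns the pair
    table (ibs0/1/2, pi_hat, flagged) and the per-flagged-pair removal list
    (lower-call-rate member).
    """
    import warnings

    if geno.n_snps < 50:
        warnings.warn("fewer than 50 SNPs: relatedness estimates are unstable")
    dos = geno.dosage
    p = geno.allele_freq()
    q = 1.0 - p
    valid = ~np.isnan(dos)
    A0 = ((dos == 0) & valid).astype(float)
    A1 = ((dos == 1) & valid).astype(float)
    A2 = ((dos == 2) & valid).astype(float)
    V = valid.astype(float)

    ibs0 = A0 @ A2.T + A2 @ A0.T
    ibs2 = A0 @ A0.T + A1 @ A1.T + A2 @ A2.T
    cocalled = V @ V.T
    ibs1 = cocalled - ibs0 - ibs2

    # per-SNP IBS expectations conditional on IBD state
    w0_ibs0 = 2 * p**2 * q**2
    w0_ibs1 = 4 * p**3 * q + 4 * p * q**3
    w1_ibs1 = 2 * p * q
    w1_ibs2 = p**2 + q**2
    # expectations restricted to each pair's co-called SNPs
    E0_ibs0 = (V * w0_ibs0) @ V.T
    E0_ibs1 = (V * w0_ibs1) @ V.T
    E1_ibs1 = (V * w1_ibs1) @ V.T
    E1_ibs2 = (V * w1_ibs2) @ V.T

    with np.errstate(divide="ignore", invalid="ignore"):
        P0 = ibs0 / E0_ibs0
        P1 = (ibs1 - E0_ibs1 * P0) / E1_ibs1
        P2 = (ibs2 - (cocalled - E0_ibs0 - E0_ibs1) * P0 - E1_ibs2 * P1) / cocalled
    P0, P1, P2 = (np.nan_to_num(x) for x in (P0, P1, P2))
    pihat = np.clip(P1 / 2 + P2, 0.0, 1.0)

    call_rate = geno.sample_call_rate()
    ids = geno.samples.index
    iu = np.triu_indices(geno.n_samples, k=1)
    table = pd.DataFrame(
        {
            "id1": ids[iu[0]],
            "id2": ids[iu[1]],
            "ibs0": ibs0[iu].astype(int),
            "ibs1": ibs1[iu].astype(int),
            "ibs2": ibs2[iu].astype(int),
            "n_cocalled": cocalled[iu].astype(int),
            "pi_hat": pihat[iu],
        }
    )
    table["flagged"] = table["pi_hat"] > pihat_max
    to_remove = []
    for _, row in table[table["flagged"]].iterrows():
        i1 = ids.get_loc(row["id1"])
        i2 = ids.get_loc(row["id2"])
        loser = row["id1"] if call_rate[i1] <= call_rate[i2] else row["id2"]
        if loser not in to_remove:
            to_remove.append(loser)
    return table, to_remove


# --------------------------------------------------------------------------- #
# PCA / population structure
# --------------------------------------------------------------------------- #

@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # final samples x axes
    eigenvalues: np.ndarray
    outliers: list
    n_iterations: int


def pca_structure(
    geno: GenotypeMatrix,
    n_axes: int = 10,
    outlier_sd: float = 6.0,
    max_iter: int = 5,
) -> PcaResult:
    """Iterative outlier-removing genotype PCA.

    Columns are standardized by mean ``2p`` and ``sqrt(2 p (1-p))``; missing
    dosages become 0 after centering.  Samples more than ``outlier_sd`` SDs
    from the mean on any retained axis are removed and the decomposition is
    recomputed, up to ``max_iter`` rounds.
    """
    import warnings

    ids = geno.samples.index
    dos = geno.dosage
    outliers: list = []
    active = np.ones(len(ids), dtype=bool)
    n_iter = 0
    coords = None
    eigvals = np.zeros(0)
    for n_iter in range(1, max_iter + 1):
        X = _standardize(dos[active])
        k = min(n_axes, min(X.shape) - 1)
        if k < n_axes:
            warnings.warn(f"rank limits axes to {k}")
        if k < 1:
            raise ValueError("not enough samples/SNPs for PCA")
        U, S, _ = np.linalg.svd(X, full_matrices=False)
        scores = U[:, :k] * S[:k]
        eigvals = (S[:k] ** 2) / max(X.shape[0] - 1, 1)
        mu = scores.mean(axis=0)
        sd = scores.std(axis=0)
        sd[sd == 0] = 1.0
        z = np.abs(scores - mu) / sd
        out_mask = (z > outlier_sd).any(axis=1)
        coords = scores
        if not out_mask.any():
            break
        new_out = ids[active][out_mask]
        outliers += list(new_out)
        active[ids.get_indexer(new_out)] = False
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PcaResult(
        coordinates=pd.DataFrame(coords, index=ids[active], columns=cols),
        eigenvalues=eigvals,
        outliers=outliers,
        n_iterations=n_iter,
    )


def _standardize(dos: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dos, axis=0) / 2.0
    p = np.where(np.isnan(p), 0.0, p)
    keep = (p > 0) & (p < 1)
    X = dos[:, keep] - 2 * p[keep]
    X[np.isnan(X)] = 0.0
    return X / np.sqrt(2 * p[keep] * (1 - p[keep]))
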