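"""Expression normalization and probe hygiene.

The analyzable probe set is produced by three ordered filters (non-autosomal,
non-specific by genomic mapping-hit count, retired annotation), and spurious
cis signals are prevented by excluding SNP-probe pairs where the SNP lies in
the probe's target interval, is in LD with such a SNP, or where an InDel
overlaps the probe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AUTOSOMES, GenotypeMatrix


@dataclass
class FilterReport:
    start: int
    removed: dict[str, int]
    kept: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"step": "input", "count": self.start}]
        rows += [{"step": f"removed_{k}", "count": v} for k, v in self.removed.items()]
        rows.append({"step": "kept", "count": self.kept})
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# normalization
# --------------------------------------------------------------------------- #

def quantile_normalize_log2(expr: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize raw intensities across samples, then log2.

    Rows are samples, columns probes.  Every sample's value of rank *r* is
    replaced by the mean over samples of the *r*-th order statistic; tied
    values within a sample receive the mean of the reference values their
    tied ranks span.  Afterwards every sample's sorted vector is identical.
    """
    X = expr.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("expression matrix must be complete")
    if (X <= 0).any():
        raise ValueError("expression intensities must be strictly positive")
    n, m = X.shape
    order = np.argsort(X, axis=1, kind="mergesort")
    sorted_vals = np.take_along_axis(X, order, axis=1)
    reference = sorted_vals.mean(axis=0)

    out = np.empty_like(X)
    for i in range(n):
        assigned = np.empty(m)
        assigned[order[i]] = reference
        row = pd.Series(assigned)
        out[i] = row.groupby(X[i], sort=False).transform("mean").to_numpy()
    return pd.DataFrame(np.log2(out), index=expr.index, columns=expr.columns)


def detect_outlier_arrays(
    expr: pd.DataFrame, sd_cut: float = 4.0, max_iter: int = 5
) -> tuple[pd.DataFrame, list]:
    """Flag arrays far out on expression PC1/PC2 and return the trimmed view.

    Samples beyond ``sd_cut`` SDs from the mean on either of the first two
    principal components are removed and the PCA repeated until stable.
    """
    if len(expr) < 10:
        warnings.warn("fewer than 10 samples: outlier-array detection skipped")
        return expr, []
    flagged: list = []
    current = expr
    for _ in range(max_iter):
        X = current.to_numpy(dtype=float)
        X = X - X.mean(axis=0)
        U, S, _ = np.linalg.svd(X, full_matrices=False)
        k = min(2, len(S))
        scores = U[:, :k] * S[:k]
        sd = scores.std(axis=0)
        sd[sd == 0] = 1.0
        z = np.abs(scores - scores.mean(axis=0)) / sd
        out = (z > sd_cut).any(axis=1)
        if not out.any():
            break
        flagged += list(current.index[out])
        current = current.loc[~out]
    return current, flagged


# --------------------------------------------------------------------------- #
# probe filters
# --------------------------------------------------------------------------- #

def filter_probes(
    annot: pd.DataFrame, autosomes: frozenset = AUTOSOMES
) -> tuple[pd.Index, FilterReport]:
    """Ordered probe-hygiene filters: non-autosomal, non-specific, retired.

    A probe is non-specific when its genomic ``mapping_hits`` count is not
    exactly 1 (no hit, or multiple high-homology hits).  Removal counts are
    reported per step in application order.
    """
    required = {"chrom", "mapping_hits", "retired"}
    if not required.issubset(annot.columns):
        raise ValueError(f"annotation missing columns {required - set(annot.columns)}")
    known = autosomes | {"X", "Y", "XY", "MT"}
    unknown = set(annot["chrom"].astype(str)) - known
    if unknown:
        raise ValueError(f"unknown chromosome labels: {sorted(unknown)[:5]}")

    start = len(annot)
    current = annot
    removed: dict[str, int] = {}

    mask = ~current["chrom"].astype(str).isin(autosomes)
    removed["non_autosomal"] = int(mask.sum())
    current = current.loc[~mask]

    mask = current["mapping_hits"] != 1
    removed["non_specific"] = int(mask.sum())
    current = current.loc[~mask]

    mask = current["retired"].astype(bool)
    removed["retired"] = int(mask.sum())
    current = current.loc[~mask]

    return current.index, FilterReport(start=start, removed=removed, kept=len(current))


# --------------------------------------------------------------------------- #
# SNP-probe pair exclusions
# --------------------------------------------------------------------------- #

def build_pair_exclusions(
    geno: GenotypeMatrix,
    annot: pd.DataFrame,
    indels: pd.DataFrame | None = None,
    r2_ld: float = 0.2,
    half_window: int = 500_000,
) -> pd.DataFrame:
    """Pairs (snp, probe) that must never be tested as cis eQTLs.

    * ``snp_in_probe``: the SNP position lies inside the probe interval;
    * ``ld_with_probe_snp``: dosage r² with any in-probe SNP of that probe
      exceeds ``r2_ld`` (searched within the cis window);
    * ``indel_overlap``: an InDel overlaps the probe interval — all of the
      probe's cis pairs are excluded.

    Lowering ``r2_ld`` can only grow the set.
    """
    if (annot["end"] < annot["start"]).any():
        bad = annot.index[annot["end"] < annot["start"]][0]
        raise ValueError(f"probe {bad}: interval end < start")
    pos = geno.snps["pos"].to_numpy()
    chrom = geno.snps["chrom"].to_numpy().astype(str)
    snp_ids = geno.snps.index.to_numpy()
    X = geno.dosage_filled()
    sd = X.std(axis=0)

    records: list[tuple[str, str, str]] = []
    for probe, row in annot.iterrows():
        pc = str(row["chrom"])
        on_chrom = np.where(chrom == pc)[0]
        if on_chrom.size == 0:
            continue
        inside = on_chrom[(pos[on_chrom] >= row["start"]) & (pos[on_chrom] <= row["end"])]
        for j in inside:
            records.append((snp_ids[j], probe, "snp_in_probe"))
        if inside.size:
            near = on_chrom[np.abs(pos[on_chrom] - int(row["midpoint"])) <= half_window]
            near = np.setdiff1d(near, inside)
            ok = near[sd[near] > 0]
            anchors = inside[sd[inside] > 0]
            if ok.size and anchors.size:
                A = X[:, anchors] - X[:, anchors].mean(axis=0)
                B = X[:, ok] - X[:, ok].mean(axis=0)
                num = A.T @ B
                den = np.outer(
                    np.sqrt((A**2).sum(axis=0)), np.sqrt((B**2).sum(axis=0))
                )
                r2 = (num / den) ** 2
                hit = ok[(r2 > r2_ld).any(axis=0)]
                for j in hit:
                    records.append((snp_ids[j], probe, "ld_with_probe_snp"))

    if indels is not None and len(indels):
        for probe, row in annot.iterrows():
            pc = str(row["chrom"])
            olap = indels[
                (indels["chrom"].astype(str) == pc)
                & (indels["end"] >= row["start"])
                & (indels["start"] <= row["end"])
            ]
            if len(olap):
                on_chrom = np.where(chrom == pc)[0]
                near = on_chrom[np.abs(pos[on_chrom] - int(row["midpoint"])) <= half_window]
                for j in near:
                    records.append((snp_ids[j], probe, "indel_overlap"))

    df = pd.DataFrame(records, columns=["snp", "probe", "reason"])
    return df.drop_duplicates(subset=["snp", "probe"], keep="first").reset_index(drop=True)
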