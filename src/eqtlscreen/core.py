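"""In-memory containers shared across the pipeline.

Genotypes are held as a dense samples x SNPs minor-allele dosage matrix
(float64, ``nan`` marking a missing call) with SNP and sample metadata as
pandas DataFrames indexed by id.  Expression matrices, annotation tables and
covariate sets are plain DataFrames; only the genotype container needs
structure of its own because dosage, SNP map and sample sheet must stay
aligned through every QC subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = np.nan

#: chromosome labels treated as autosomal throughout the package
AUTOSOMES = frozenset(str(c) for c in range(1, 23))


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele dosages in {0, 1, 2, nan}.

    ``snps`` is indexed by SNP id with columns ``chrom`` (str), ``pos``
    (1-based bp, int), ``a1``/``a2`` (minor/major allele).  ``samples`` is
    indexed by sample id; the pipeline expects at least ``status`` (0/1),
    ``sex`` (0/1) and ``cohort`` where the respective stage needs them.
    """

    dosage: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x SNPs)")
        if self.dosage.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if self.samples.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.snps.index.has_duplicates:
            raise ValueError("duplicate SNP ids")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosage < 0) | (self.dosage > 2))
        if bad:
            raise ValueError("dosages outside {0,1,2,nan}")

    # ------------------------------------------------------------------ sizes
    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    # ------------------------------------------------------------- statistics
    def allele_freq(self) -> np.ndarray:
        """Frequency of the coded (a1) allele per SNP, ignoring missing."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def snp_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosage), axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosage), axis=1)

    def dosage_filled(self) -> np.ndarray:
        """Dosage with missing entries replaced by the per-SNP mean."""
        X = self.dosage.copy()
        if np.isnan(X).any():
            col_mean = np.nanmean(X, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(X))
            X[idx] = col_mean[idx[1]]
        return X

    # --------------------------------------------------------------- indexing
    def subset_samples(self, ids: Sequence) -> "GenotypeMatrix":
        ids = pd.Index(ids)
        pos = self.samples.index.get_indexer(ids)
        if (pos < 0).any():
            missing = ids[pos < 0].tolist()
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return GenotypeMatrix(self.dosage[pos], self.snps.copy(), self.samples.loc[ids].copy())

    def subset_snps(self, ids: Sequence) -> "GenotypeMatrix":
        ids = pd.Index(ids)
        pos = self.snps.index.get_indexer(ids)
        if (pos < 0).any():
            missing = ids[pos < 0].tolist()
            raise KeyError(f"unknown SNP ids: {missing[:5]}")
        return GenotypeMatrix(self.dosage[:, pos], self.snps.loc[ids].copy(), self.samples.copy())

    def drop_samples(self, ids: Iterable) -> "GenotypeMatrix":
        keep = self.samples.index.difference(pd.Index(ids), sort=False)
        return self.subset_samples(keep)

    def recode_minor(self) -> "GenotypeMatrix":
        """Flip coding so a1 is the minor allele observed in this sample set."""
        f = self.allele_freq()
        flip = f > 0.5
        dos = self.dosage.copy()
        dos[:, flip] = 2.0 - dos[:, flip]
        snps = self.snps.copy()
        a1 = snps["a1"].to_numpy().copy()
        a2 = snps["a2"].to_numpy().copy()
        a1[flip], a2[flip] = a2[flip].copy(), a1[flip].copy()
        snps["a1"], snps["a2"] = a1, a2
        if "gen_freq" in snps.columns:  # generating frequency follows the coded allele
            gf = snps["gen_freq"].to_numpy().copy()
            gf[flip] = 1.0 - gf[flip]
            snps["gen_freq"] = gf
        return GenotypeMatrix(dos, snps, self.samples.copy())

    def sort_canonical(self) -> "GenotypeMatrix":
        """Lexicographic sample order, (chrom, pos) SNP order."""
        samp = self.samples.sort_index()
        key = self.snps.assign(_c=self.snps["chrom"].map(_chrom_sort_key))
        snp_ids = key.sort_values(["_c", "pos"]).index
        return self.subset_samples(samp.index).subset_snps(snp_ids)


def _chrom_sort_key(c: str) -> int:
    c = str(c)
    if c.isdigit():
        return int(c)
    return {"X": 23, "Y": 24, "XY": 25, "MT": 26}.get(c, 99)


@dataclass
class StudyBundle:
    """One analysis dataset: genotypes plus optional expression-side tables."""

    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    expression: pd.DataFrame | None = None
    probe_annotation: pd.DataFrame | None = None
    covariates: pd.DataFrame | None = None
    indels: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def sample_ids(self) -> pd.Index:
        return self.genotypes.samples.index
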