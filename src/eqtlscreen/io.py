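"""Readers and writers for the standard formats the pipeline touches.

Genotypes travel as PLINK 1.9 binary (BED magic ``6c 1b``, SNP-major) with
BIM/FAM side files, or as text PED/MAP.  All tabular side data are
tab-separated with a header row.  Coordinates are 1-based inclusive (the BIM
convention).  On load, samples and SNPs are put into canonical order
(lexicographic sample ids, (chrom, pos) SNPs) so that permuting the row order
of the input files yields the same bundle.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, StudyBundle

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # v1.9, SNP-major
# 2-bit PLINK codes -> dosage of allele A1
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


# --------------------------------------------------------------------------- #
# PLINK binary
# --------------------------------------------------------------------------- #

def write_plink(
    geno: GenotypeMatrix, prefix: str | Path, phenotypes: pd.DataFrame | None = None
) -> None:
    """Write BED/BIM/FAM at ``prefix``.{bed,bim,fam}."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = geno.n_samples, geno.n_snps

    # FAM: fid iid pat mat sex pheno (sex 1=male 2=female 0=unknown; pheno 1/2)
    samp = geno.samples
    if phenotypes is not None:
        samp = samp.join(phenotypes[[c for c in phenotypes.columns if c not in samp.columns]])
    sex = samp["sex"] + 1 if "sex" in samp else pd.Series(0, index=samp.index)
    status = samp["status"] + 1 if "status" in samp else pd.Series(-9, index=samp.index)
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for iid, sx, st in zip(samp.index, sex, status):
            fh.write(f"{iid} {iid} 0 0 {int(sx)} {int(st)}\n")

    with open(prefix.with_suffix(".bim"), "w") as fh:
        for sid, row in geno.snps.iterrows():
            fh.write(f"{row['chrom']}\t{sid}\t0\t{int(row['pos'])}\t{row['a1']}\t{row['a2']}\n")

    dos = geno.dosage
    nbytes = (n + 3) // 4
    out = np.empty((m, nbytes), dtype=np.uint8)
    codes = np.full((m, n), 0b01, dtype=np.uint8)  # missing
    for val, code in _DOSAGE_TO_CODE.items():
        codes[(dos.T == val)] = code
    padded = np.zeros((m, nbytes * 4), dtype=np.uint8)
    padded[:, :n] = codes
    out = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(out.tobytes())


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read BED/BIM/FAM from ``prefix``.{bed,bim,fam} (canonical order)."""
    prefix = Path(prefix)
    snps = _read_bim(prefix.with_suffix(".bim"))
    samples = _read_fam(prefix.with_suffix(".fam"))
    n, m = len(samples), len(snps)

    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK 1.9 BED file")
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    nbytes = (n + 3) // 4
    if body.size != m * nbytes:
        raise ValueError(f"{prefix}.bed: size mismatch ({body.size} bytes, expected {m * nbytes})")
    body = body.reshape(m, nbytes)
    codes = np.empty((m, nbytes * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0b11
    codes[:, 1::4] = (body >> 2) & 0b11
    codes[:, 2::4] = (body >> 4) & 0b11
    codes[:, 3::4] = (body >> 6) & 0b11
    dosage = _CODE_TO_DOSAGE[codes[:, :n]].T
    return GenotypeMatrix(dosage, snps, samples).sort_canonical()


def _read_bim(path: Path) -> pd.DataFrame:
    rows, ids = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"{path}:{ln}: malformed BIM line ({len(parts)} fields)")
            chrom, sid, _cm, pos, a1, a2 = parts
            try:
                pos = int(pos)
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: non-integer position {pos!r}") from e
            ids.append(sid)
            rows.append({"chrom": chrom, "pos": pos, "a1": a1, "a2": a2})
    df = pd.DataFrame(rows, index=pd.Index(ids, name="snp"))
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate SNP ids")
    return df


def _read_fam(path: Path) -> pd.DataFrame:
    rows, ids = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"{path}:{ln}: malformed FAM line ({len(parts)} fields)")
            _fid, iid, _pat, _mat, sex, pheno = parts
            rows.append(
                {
                    "sex": int(sex) - 1 if sex in ("1", "2") else -9,
                    "status": int(pheno) - 1 if pheno in ("1", "2") else -9,
                }
            )
            ids.append(iid)
    df = pd.DataFrame(rows, index=pd.Index(ids, name="sample"))
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    return df


# --------------------------------------------------------------------------- #
# PED/MAP text
# --------------------------------------------------------------------------- #

def write_ped_map(geno: GenotypeMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for sid, row in geno.snps.iterrows():
            fh.write(f"{row['chrom']}\t{sid}\t0\t{int(row['pos'])}\n")
    a1 = geno.snps["a1"].to_numpy()
    a2 = geno.snps["a2"].to_numpy()
    samp = geno.samples
    sex = samp["sex"] + 1 if "sex" in samp else pd.Series(0, index=samp.index)
    status = samp["status"] + 1 if "status" in samp else pd.Series(-9, index=samp.index)
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, iid in enumerate(samp.index):
            fields = [str(iid), str(iid), "0", "0", str(int(sex.iloc[i])), str(int(status.iloc[i]))]
            for j in range(geno.n_snps):
                d = geno.dosage[i, j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 2:
                    fields += [a1[j], a1[j]]
                elif d == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")


def read_ped_map(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    rows, ids = [], []
    with open(prefix.with_suffix(".map")) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{prefix}.map:{ln}: malformed MAP line")
            rows.append({"chrom": parts[0], "pos": int(parts[3]), "a1": "?", "a2": "?"})
            ids.append(parts[1])
    snps = pd.DataFrame(rows, index=pd.Index(ids, name="snp"))
    m = len(snps)

    sample_ids, meta, genos = [], [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{prefix}.ped:{ln}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            meta.append(
                {
                    "sex": int(parts[4]) - 1 if parts[4] in ("1", "2") else -9,
                    "status": int(parts[5]) - 1 if parts[5] in ("1", "2") else -9,
                }
            )
            genos.append(parts[6:])
    alleles = np.array(genos, dtype="U2").reshape(len(sample_ids), m, 2)

    dosage = np.full((len(sample_ids), m), np.nan)
    a1 = np.empty(m, dtype=object)
    a2 = np.empty(m, dtype=object)
    for j in range(m):
        col = alleles[:, j, :]
        called = col[col != "0"]
        uniq = pd.unique(called)
        if uniq.size > 2:
            raise ValueError(f"{prefix}.ped: SNP {snps.index[j]} has >2 alleles")
        counts = {u: int((called == u).sum()) for u in uniq}
        order = sorted(counts, key=lambda u: (counts[u], str(u)))
        minor = order[0] if order else "A"
        major = order[-1] if len(order) > 1 else minor
        a1[j], a2[j] = minor, major
        miss = (col == "0").any(axis=1)
        d = (col == minor).sum(axis=1).astype(float)
        d[miss] = np.nan
        dosage[:, j] = d
    snps["a1"], snps["a2"] = a1, a2
    samples = pd.DataFrame(meta, index=pd.Index(sample_ids, name="sample"))
    if samples.index.has_duplicates:
        raise ValueError(f"{prefix}.ped: duplicate sample ids")
    return GenotypeMatrix(dosage, snps, samples).sort_canonical().recode_minor()


# --------------------------------------------------------------------------- #
# tabular side files
# --------------------------------------------------------------------------- #

def read_tsv_indexed(path: str | Path, index_col: str) -> pd.DataFrame:
    """Strict TSV reader: header required, no ragged or missing cells."""
    df = pd.read_csv(path, sep="\t", index_col=index_col)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing or ragged cells")
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate ids in column {index_col!r}")
    return df


def load_study_bundle(paths: dict[str, str | Path], intersect: bool = True) -> StudyBundle:
    """Assemble a :class:`StudyBundle` from files.

    ``paths`` keys: ``plink`` (prefix) or ``ped`` (prefix), plus optional
    ``phenotypes``, ``expression``, ``probe_annotation``, ``covariates``,
    ``indels``.  With ``intersect=True`` all members are restricted to the
    sample ids common to every table; dropped ids are recorded in provenance.
    """
    if "plink" in paths:
        geno = read_plink(paths["plink"])
    elif "ped" in paths:
        geno = read_ped_map(paths["ped"])
    else:
        raise ValueError("paths must contain 'plink' or 'ped'")

    pheno = (
        read_tsv_indexed(paths["phenotypes"], "sample")
        if "phenotypes" in paths
        else geno.samples.copy()
    )
    expr = read_tsv_indexed(paths["expression"], "sample") if "expression" in paths else None
    annot = (
        read_tsv_indexed(paths["probe_annotation"], "probe")
        if "probe_annotation" in paths
        else None
    )
    covs = read_tsv_indexed(paths["covariates"], "sample") if "covariates" in paths else None
    indels = pd.read_csv(paths["indels"], sep="\t") if "indels" in paths else None

    dropped: list[str] = []
    if intersect:
        common = geno.samples.index.intersection(pheno.index)
        if expr is not None:
            common = common.intersection(expr.index)
        if covs is not None:
            common = common.intersection(covs.index)
        common = common.sort_values()
        for tbl in (geno.samples, pheno) + ((expr,) if expr is not None else ()):
            dropped += [i for i in tbl.index if i not in set(common)]
        geno = geno.subset_samples(common)
        pheno = pheno.loc[common]
        if expr is not None:
            expr = expr.loc[common]
        if covs is not None:
            covs = covs.loc[common]

    prov = {
        "paths": {k: str(v) for k, v in paths.items()},
        "checksums": {
            k: _checksum(v)
            for k, v in paths.items()
            if k not in ("plink", "ped") and Path(v).is_file()
        },
        "dropped_samples": sorted(set(dropped)),
    }
    return StudyBundle(
        genotypes=geno,
        phenotypes=pheno,
        expression=expr,
        probe_annotation=annot,
        covariates=covs,
        indels=indels,
        provenance=prov,
    )


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


# --------------------------------------------------------------------------- #
# run reports
# --------------------------------------------------------------------------- #

def write_reports(report, directory: str | Path) -> dict[str, Path]:
    """Persist a pipeline run: per-stage TSVs, a JSON count summary keyed by
    the study-design stages, and a plain-text narrative.  Idempotent: writing
    the same run twice produces byte-identical files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for name, table in sorted(report.tables.items()):
        p = directory / f"{name}.tsv"
        table.to_csv(p, sep="\t", index=False)
        paths[name] = p

    counts_path = directory / "stage_counts.json"
    with open(counts_path, "w") as fh:
        json.dump(report.counts, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["stage_counts"] = counts_path

    narrative = directory / "run_report.txt"
    lines = ["two-stage eQTL/GWAS run", "=" * 23]
    for stage, value in report.counts.items():
        lines.append(f"{stage}: {value}")
    for stage in report.incomplete:
        lines.append(f"{stage}: ABSENT (stage did not complete)")
    narrative.write_text("\n".join(lines) + "\n")
    paths["narrative"] = narrative
    return paths
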