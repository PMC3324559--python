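"""Seeded synthetic study-bundle generator.

Emulates the statistical structure the analysis assumes, so that every
pipeline stage is testable without any external download:

* biallelic autosomal SNPs arranged in LD blocks: per block a small pool of
  founder haplotypes is drawn, and each individual is the union of two
  haplotypes sampled from the pool — within-block LD, between-block
  near-independence, and Hardy–Weinberg proportions conditional on the pool;
* two-subpopulation structure via Balding–Nichols drift of the block allele
  frequencies (parameter ``fst``), which makes the subpopulations separable
  by genotype PCA;
* case/control status from a logistic model on designated risk SNPs;
* expression = probe baseline + planted cis effects (``cis_beta`` per copy of
  the minor allele, in residual-SD units) + batch offsets + N(0,1) noise,
  exponentiated to a positive raw-intensity scale so the normalization stage
  has real work to do;
* probe artifacts (non-autosomal, non-specific, retired, SNP-in-probe,
  InDel-overlapped) planted in the annotation table for the hygiene filters.

Identical :class:`SimulationConfig` (including seed) yields byte-identical
bundles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .core import GenotypeMatrix, StudyBundle

PROBE_HALF_LEN = 25  # bp; Illumina-style 50-mer probes


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Cohort sizes default to the expression-profiled ALS cohort this package
    models (162 cases / 207 controls per eQTL stage); GWAS-stage sizes default
    to the genotype-only replication cohort scale.  Genomic sizes default to a
    desk-scale panel; all counts are free knobs.
    """

    seed: int = 0
    # eQTL-stage cohort (samples with both genotypes and expression)
    n_cases: int = 162
    n_controls: int = 207
    # genotype-only GWAS-stage cohort sizes (per stage) for two-stage bundles
    n_gwas_cases: int = 1000
    n_gwas_controls: int = 1400
    n_snps: int = 5000
    n_probes: int = 1000
    n_chromosomes: int = 22
    block_size: int = 10
    n_founder_haplotypes: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    fst: float = 0.01
    admix_fraction: float = 0.3
    n_risk_snps: int = 5
    risk_or: float = 1.2
    n_cis_effects: int = 50
    cis_beta: float = 1.0
    #: how many risk SNPs double as planted cis-eQTL SNPs (end-to-end signal)
    n_overlap_risk_cis: int = 0
    n_batches: int = 4
    batch_sd: float = 0.5
    missing_rate: float = 0.01
    #: probes per artifact class: non_autosomal, non_specific, retired,
    #: snp_in_probe, indel_overlap.  None derives counts from n_probes at the
    #: array-realistic fractions (4.1% / 14.8% / 5% / 2% / 2.5%).
    artifact_counts: dict | None = None
    snp_spacing: int = 5000  # bp between adjacent SNPs on a chromosome

    _ARTIFACT_FRACTIONS = {
        "non_autosomal": 0.041,
        "non_specific": 0.148,
        "retired": 0.050,
        "snp_in_probe": 0.020,
        "indel_overlap": 0.025,
    }

    def resolved_artifact_counts(self) -> dict:
        if self.artifact_counts is not None:
            return self.artifact_counts
        return {k: int(round(f * self.n_probes)) for k, f in self._ARTIFACT_FRACTIONS.items()}

    def validate(self) -> None:
        if self.n_cases + self.n_controls <= 0:
            raise ValueError("zero samples configured")
        if self.n_snps <= 0:
            raise ValueError("zero SNPs configured")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.fst <= 0.2):
            raise ValueError("fst must lie in [0, 0.2]")
        if not (0 <= self.missing_rate <= 0.1):
            raise ValueError("missing_rate must lie in [0, 0.1]")
        if self.n_cis_effects > self.n_probes:
            raise ValueError("n_cis_effects exceeds n_probes")
        if self.n_risk_snps > self.n_snps:
            raise ValueError("n_risk_snps exceeds n_snps")
        if self.n_overlap_risk_cis > min(self.n_risk_snps, self.n_cis_effects):
            raise ValueError("n_overlap_risk_cis exceeds risk/cis counts")
        for k, v in self.resolved_artifact_counts().items():
            if v < 0:
                raise ValueError(f"negative artifact count for {k}")
        if self.block_size < 1 or self.n_founder_haplotypes < 2:
            raise ValueError("block_size >= 1 and n_founder_haplotypes >= 2 required")


@dataclass
class TruthTable:
    """Ground truth of the planted signals, for parameter-recovery tests."""

    cis_pairs: pd.DataFrame  # snp, probe, beta
    risk_snps: pd.DataFrame  # snp, log_or
    batch: pd.Series  # per sample id
    subpop: pd.Series  # per sample id

    def validate_against(self, geno: GenotypeMatrix, probes: pd.Index) -> None:
        if not set(self.cis_pairs["snp"]).issubset(geno.snps.index):
            raise ValueError("truth cis pair references unknown SNP")
        if not set(self.cis_pairs["probe"]).issubset(probes):
            raise ValueError("truth cis pair references unknown probe")
        if not np.isfinite(self.cis_pairs["beta"]).all():
            raise ValueError("non-finite planted beta")


# --------------------------------------------------------------------------- #
# genotypes
# --------------------------------------------------------------------------- #

def simulate_genotypes(config: SimulationConfig, n_samples: int | None = None) -> GenotypeMatrix:
    """Draw the genotype matrix for ``n_samples`` individuals (default
    ``n_cases + n_controls``) from block-structured founder-haplotype pools.

    Within each LD block every individual receives two haplotypes sampled
    with replacement from the block's founder pool of its subpopulation;
    subpopulation allele frequencies are drifted from a common ancestral
    frequency by the Balding–Nichols model with parameter ``fst``.
    """
    config.validate()
    n = n_samples if n_samples is not None else config.n_cases + config.n_controls
    if n <= 0:
        raise ValueError("zero samples requested")
    rng = np.random.default_rng([config.seed, 11])

    subpop = (rng.random(n) < config.admix_fraction).astype(int)

    chrom, pos = _snp_layout(config)
    dosage = np.empty((n, config.n_snps), dtype=float)

    lo, hi = config.maf_range
    H = config.n_founder_haplotypes
    gen_freq = np.zeros(config.n_snps)  # pool frequency actually sampled from
    w = np.array([(subpop == 0).mean(), (subpop == 1).mean()])
    start = 0
    while start < config.n_snps:
        # blocks never span chromosomes
        end = min(start + config.block_size, config.n_snps)
        c = chrom[start]
        while end > start and chrom[end - 1] != c:
            end -= 1
        bs = end - start
        p_anc = rng.uniform(lo, hi, size=bs)
        if config.fst == 0:
            # no drift: one shared founder pool, hence no structure at all
            pool = rng.random((H, bs)) < p_anc
            gen_freq[start:end] = pool.mean(axis=0)
            picks = rng.integers(0, H, size=(n, 2))
            dosage[:, start:end] = pool[picks[:, 0]].astype(float) + pool[picks[:, 1]]
        else:
            for k in (0, 1):
                members = np.where(subpop == k)[0]
                p_k = _balding_nichols(rng, p_anc, config.fst)
                pool = rng.random((H, bs)) < p_k  # founder haplotypes
                gen_freq[start:end] += w[k] * pool.mean(axis=0)
                if members.size:
                    picks = rng.integers(0, H, size=(members.size, 2))
                    dosage[members, start:end] = (
                        pool[picks[:, 0]].astype(float) + pool[picks[:, 1]]
                    )
        start = end

    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    snps = pd.DataFrame(
        {
            "chrom": chrom.astype(str),
            "pos": pos,
            "a1": "A",
            "a2": "G",
            "gen_freq": gen_freq,
        },
        index=pd.Index([f"rs{i:06d}" for i in range(config.n_snps)], name="snp"),
    )
    samples = pd.DataFrame(
        {"subpop": subpop},
        index=pd.Index([f"S{i:05d}" for i in range(n)], name="sample"),
    )
    return GenotypeMatrix(dosage, snps, samples).recode_minor()


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, fst: float) -> np.ndarray:
    if fst <= 0:
        return p
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    return np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)


def _snp_layout(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Spread SNPs over chromosomes in contiguous, evenly spaced runs."""
    per = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    per[: config.n_snps % config.n_chromosomes] += 1
    chrom = np.repeat(np.arange(1, config.n_chromosomes + 1), per)
    pos = np.concatenate(
        [10_000 + config.snp_spacing * np.arange(k) for k in per]
    ).astype(np.int64)
    return chrom, pos


# --------------------------------------------------------------------------- #
# phenotype, expression, annotations
# --------------------------------------------------------------------------- #

def simulate_phenotype_and_expression(
    geno: GenotypeMatrix, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthTable]:
    """Plant phenotype, expression, probe annotations and artifacts.

    Returns ``(phenotypes, expression, probe_annotation, indels, truth)``.
    Case/control status is Bernoulli with logit = b0 + sum(log OR x dosage)
    over the designated risk SNPs, b0 chosen so the expected case fraction
    matches ``n_cases / (n_cases + n_controls)``.  Expression is generated on
    a log2-like scale and exponentiated to positive raw intensities.
    """
    config.validate()
    if geno.n_samples == 0:
        raise ValueError("no genotypes supplied")
    if config.risk_or <= 0:
        raise ValueError("risk_or must be positive")
    rng = np.random.default_rng([config.seed, 23])
    n = geno.n_samples
    X = geno.dosage_filled()
    maf = geno.maf()

    # ---- risk SNPs and case/control status
    eligible = np.where(maf >= 0.1)[0]
    if eligible.size < config.n_risk_snps:
        eligible = np.arange(geno.n_snps)
    risk_idx = np.sort(rng.choice(eligible, size=config.n_risk_snps, replace=False))
    log_or = np.full(config.n_risk_snps, np.log(config.risk_or))
    eta = X[:, risk_idx] @ log_or if config.n_risk_snps else np.zeros(n)
    target = config.n_cases / (config.n_cases + config.n_controls)
    b0 = _solve_intercept(eta, target)
    status = (rng.random(n) < expit(b0 + eta)).astype(int)

    # ---- probe layout: cis probes sit near their partner SNP
    cis_snp_idx = _pick_cis_snps(rng, config, risk_idx, maf)
    probe_ids = pd.Index([f"ILMN_{i:06d}" for i in range(config.n_probes)], name="probe")
    cis_probe_pos = rng.choice(config.n_probes, size=config.n_cis_effects, replace=False)
    chrom = np.empty(config.n_probes, dtype=object)
    mid = np.empty(config.n_probes, dtype=np.int64)
    # background probes anywhere on the autosomes
    bg_snp = rng.integers(0, geno.n_snps, size=config.n_probes)
    chrom[:] = geno.snps["chrom"].to_numpy()[bg_snp]
    mid[:] = geno.snps["pos"].to_numpy()[bg_snp] + rng.integers(
        -400_000, 400_000, size=config.n_probes
    )
    # planted cis probes within +/-200 kb of their SNP
    snp_pos = geno.snps["pos"].to_numpy()
    snp_chrom = geno.snps["chrom"].to_numpy()
    chrom[cis_probe_pos] = snp_chrom[cis_snp_idx]
    mid[cis_probe_pos] = snp_pos[cis_snp_idx] + rng.integers(
        -200_000, 200_000, size=config.n_cis_effects
    )
    mid = np.maximum(mid, PROBE_HALF_LEN + 1)
    start = mid - PROBE_HALF_LEN
    end = mid + PROBE_HALF_LEN - 1

    annot = pd.DataFrame(
        {
            "chrom": chrom.astype(str),
            "start": start,
            "end": end,
            "midpoint": (start + end) // 2,
            "gene": [f"GENE{i:05d}" for i in range(config.n_probes)],
            "mapping_hits": 1,
            "retired": 0,
        },
        index=probe_ids,
    )

    indels = _plant_artifacts(rng, config, annot, geno, set(cis_probe_pos))

    # ---- expression
    batch = rng.integers(0, max(config.n_batches, 1), size=n)
    batch_offsets = rng.normal(0.0, config.batch_sd, size=(max(config.n_batches, 1), config.n_probes))
    baseline = rng.normal(8.0, 1.0, size=config.n_probes)
    signal = baseline + batch_offsets[batch] + rng.normal(0.0, 1.0, size=(n, config.n_probes))
    for j, (s_idx, p_pos) in enumerate(zip(cis_snp_idx, cis_probe_pos)):
        signal[:, p_pos] += config.cis_beta * X[:, s_idx]
    expression = pd.DataFrame(
        np.exp2(signal), index=geno.samples.index, columns=probe_ids
    )

    # ---- phenotype table
    sex = rng.integers(0, 2, size=n)
    age = np.round(rng.normal(60.0, 10.0, size=n), 1)
    riluzole = np.where(status == 1, rng.random(n) < 0.7, False).astype(int)
    phenotypes = pd.DataFrame(
        {
            "status": status,
            "sex": sex,
            "age": age,
            "riluzole": riluzole,
            "cohort": np.where(geno.samples["subpop"].to_numpy() == 1, "C2", "C1"),
        },
        index=geno.samples.index,
    )

    truth = TruthTable(
        cis_pairs=pd.DataFrame(
            {
                "snp": geno.snps.index.to_numpy()[cis_snp_idx],
                "probe": probe_ids.to_numpy()[cis_probe_pos],
                "beta": config.cis_beta,
            }
        ),
        risk_snps=pd.DataFrame(
            {"snp": geno.snps.index.to_numpy()[risk_idx], "log_or": log_or}
        ),
        batch=pd.Series(batch, index=geno.samples.index, name="batch"),
        subpop=pd.Series(
            geno.samples["subpop"].to_numpy(), index=geno.samples.index, name="subpop"
        ),
    )
    truth.validate_against(geno, probe_ids)
    return phenotypes, expression, annot, indels, truth


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    f = lambda b0: float(np.mean(expit(b0 + eta))) - target
    return brentq(f, -30.0, 30.0)


def _pick_cis_snps(
    rng: np.random.Generator,
    config: SimulationConfig,
    risk_idx: np.ndarray,
    maf: np.ndarray,
) -> np.ndarray:
    k = config.n_overlap_risk_cis
    overlap = risk_idx[:k]
    # plant effects on segregating SNPs only (an eQTL needs allele variation)
    rest_pool = np.setdiff1d(np.where(maf >= 0.05)[0], overlap)
    if rest_pool.size < config.n_cis_effects - k:
        rest_pool = np.setdiff1d(np.where(maf > 0)[0], overlap)
    rest = rng.choice(rest_pool, size=config.n_cis_effects - k, replace=False)
    return np.concatenate([overlap, rest]).astype(int)


def _plant_artifacts(
    rng: np.random.Generator,
    config: SimulationConfig,
    annot: pd.DataFrame,
    geno: GenotypeMatrix,
    protected: set[int],
) -> pd.DataFrame:
    """Mutate ``annot`` in place to carry the configured artifact classes and
    return the InDel table.  Artifact probes are disjoint and never overlap
    the planted cis probes."""
    counts = config.resolved_artifact_counts()
    need = sum(counts.values())
    pool = [i for i in range(len(annot)) if i not in protected]
    if need > len(pool):
        raise ValueError("artifact_counts exceed available background probes")
    chosen = rng.choice(pool, size=need, replace=False)
    groups: dict[str, np.ndarray] = {}
    off = 0
    for key in ("non_autosomal", "non_specific", "retired", "snp_in_probe", "indel_overlap"):
        k = counts.get(key, 0)
        groups[key] = chosen[off : off + k]
        off += k

    if len(groups["non_autosomal"]):
        annot.iloc[groups["non_autosomal"], annot.columns.get_loc("chrom")] = "X"
    if len(groups["non_specific"]):
        hits = rng.choice([0, 2, 3], size=len(groups["non_specific"]))
        annot.iloc[groups["non_specific"], annot.columns.get_loc("mapping_hits")] = hits
    if len(groups["retired"]):
        annot.iloc[groups["retired"], annot.columns.get_loc("retired")] = 1

    # SNP-in-probe: relocate the probe interval onto a random SNP position
    snp_pos = geno.snps["pos"].to_numpy()
    snp_chrom = geno.snps["chrom"].to_numpy()
    for i in groups["snp_in_probe"]:
        j = rng.integers(0, geno.n_snps)
        s = max(int(snp_pos[j]) - 10, 1)
        annot.iloc[i, annot.columns.get_loc("chrom")] = snp_chrom[j]
        annot.iloc[i, annot.columns.get_loc("start")] = s
        annot.iloc[i, annot.columns.get_loc("end")] = s + 2 * PROBE_HALF_LEN - 1
        annot.iloc[i, annot.columns.get_loc("midpoint")] = (2 * s + 2 * PROBE_HALF_LEN - 1) // 2

    rows = []
    for i in groups["indel_overlap"]:
        s = int(annot.iloc[i]["start"])
        rows.append(
            {
                "indel": f"indel{i:05d}",
                "chrom": str(annot.iloc[i]["chrom"]),
                "start": s,
                "end": s + int(rng.integers(1, 10)),
            }
        )
    indels = pd.DataFrame(rows, columns=["indel", "chrom", "start", "end"])
    return indels


# --------------------------------------------------------------------------- #
# bundles
# --------------------------------------------------------------------------- #

def simulate_bundle(config: SimulationConfig) -> tuple[StudyBundle, TruthTable]:
    """One self-contained bundle: genotypes + phenotype + expression + tables."""
    geno = simulate_genotypes(config)
    pheno, expr, annot, indels, truth = simulate_phenotype_and_expression(geno, config)
    geno.samples = geno.samples.join(pheno[["status", "sex", "cohort"]])
    bundle = StudyBundle(
        genotypes=geno,
        phenotypes=pheno,
        expression=expr,
        probe_annotation=annot,
        indels=indels,
        provenance={"seed": config.seed, "generator": "eqtlscreen.simulate"},
    )
    return bundle, truth


def simulate_two_stage_bundles(
    config: SimulationConfig,
) -> tuple[dict[str, StudyBundle], TruthTable]:
    """Four bundles sharing one SNP panel and founder pools: eQTL discovery /
    replication (genotypes + expression) and GWAS discovery / replication
    (genotypes only), as in a two-stage expression-anchored association study.
    """
    n_eqtl = config.n_cases + config.n_controls
    n_gwas = config.n_gwas_cases + config.n_gwas_controls
    total = 2 * n_eqtl + 2 * n_gwas
    geno = simulate_genotypes(config, n_samples=total)
    pheno, expr, annot, indels, truth = simulate_phenotype_and_expression(geno, config)
    geno.samples = geno.samples.join(pheno[["status", "sex", "cohort"]])

    ids = geno.samples.index
    splits = {
        "eqtl_discovery": ids[:n_eqtl],
        "eqtl_replication": ids[n_eqtl : 2 * n_eqtl],
        "gwas_discovery": ids[2 * n_eqtl : 2 * n_eqtl + n_gwas],
        "gwas_replication": ids[2 * n_eqtl + n_gwas :],
    }
    bundles = {}
    for name, sub in splits.items():
        g = geno.subset_samples(sub).recode_minor()
        has_expr = name.startswith("eqtl")
        bundles[name] = StudyBundle(
            genotypes=g,
            phenotypes=pheno.loc[sub].copy(),
            expression=expr.loc[sub].copy() if has_expr else None,
            probe_annotation=annot.copy() if has_expr else None,
            indels=indels.copy() if has_expr else None,
            provenance={"seed": config.seed, "split": name},
        )
    return bundles, truth


def write_fixture_set(
    bundle: StudyBundle, directory: str | Path, truth: TruthTable | None = None
) -> dict[str, Path]:
    """Write a bundle as PLINK BED/BIM/FAM plus TSV side tables.

    Round-trips losslessly through :func:`eqtlscreen.io.load_study_bundle`.
    """
    from . import io as eio  # local import to avoid a cycle

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    prefix = directory / "study"
    eio.write_plink(bundle.genotypes, prefix, phenotypes=bundle.phenotypes)
    paths.update({"bed": prefix.with_suffix(".bed"), "bim": prefix.with_suffix(".bim"),
                  "fam": prefix.with_suffix(".fam")})

    def _tsv(name: str, df: pd.DataFrame, index_label: str) -> None:
        p = directory / name
        df.to_csv(p, sep="\t", index=True, index_label=index_label)
        paths[name] = p

    _tsv("phenotypes.tsv", bundle.phenotypes, "sample")
    if bundle.expression is not None:
        _tsv("expression.tsv", bundle.expression, "sample")
    if bundle.probe_annotation is not None:
        _tsv("probe_annotation.tsv", bundle.probe_annotation, "probe")
    if bundle.indels is not None and len(bundle.indels):
        p = directory / "indels.tsv"
        bundle.indels.to_csv(p, sep="\t", index=False)
        paths["indels.tsv"] = p
    if truth is not None:
        p = directory / "truth_cis_pairs.tsv"
        truth.cis_pairs.to_csv(p, sep="\t", index=False)
        paths["truth_cis_pairs.tsv"] = p
        p = directory / "truth_risk_snps.tsv"
        truth.risk_snps.to_csv(p, sep="\t", index=False)
        paths["truth_risk_snps.tsv"] = p
    return paths
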