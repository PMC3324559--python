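import numpy as np
import pandas as pd
import pytest

from eqtlscreen.simulate import SimulationConfig, simulate_bundle

NO_ARTIFACTS = {
    "non_autosomal": 0,
    "non_specific": 0,
    "retired": 0,
    "snp_in_probe": 0,
    "indel_overlap": 0,
}


def small_config(**overrides) -> SimulationConfig:
    """Desk-scale config used across the suite; overridable per test."""
    base = dict(
        seed=0,
        n_cases=100,
        n_controls=100,
        n_snps=400,
        n_probes=60,
        n_chromosomes=4,
        n_cis_effects=0,
        n_risk_snps=0,
        missing_rate=0.0,
        fst=0.0,
        admix_fraction=0.0,
        artifact_counts=dict(NO_ARTIFACTS),
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def planted_bundle():
    """One bundle with strong planted cis effects, shared by read-only tests."""
    cfg = small_config(
        seed=3,
        n_cases=200,
        n_controls=200,
        n_cis_effects=5,
        cis_beta=1.0,
        n_batches=3,
        batch_sd=0.8,
    )
    bundle, truth = simulate_bundle(cfg)
    return cfg, bundle, truth


@pytest.fixture
def toy_genotypes():
    """Hand-built 6-sample x 4-SNP genotype matrix."""
    from eqtlscreen.core import GenotypeMatrix

    dosage = np.array(
        [
            [0, 1, 2, 0],
            [1, 1, 0, 0],
            [2, 0, 1, 1],
            [0, 2, 2, 0],
            [1, 0, 0, 2],
            [np.nan, 1, 1, 0],
        ],
        dtype=float,
    )
    snps = pd.DataFrame(
        {
            "chrom": ["1", "1", "2", "2"],
            "pos": [100, 200, 100, 5000],
            "a1": ["A", "A", "A", "A"],
            "a2": ["G", "G", "G", "G"],
        },
        index=pd.Index([f"rs{i}" for i in range(4)], name="snp"),
    )
    samples = pd.DataFrame(
        {"status": [0, 0, 0, 1, 1, 1], "sex": [0, 1, 0, 1, 0, 1]},
        index=pd.Index([f"S{i}" for i in range(6)], name="sample"),
    )
    return GenotypeMatrix(dosage, snps, samples)
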