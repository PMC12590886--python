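import numpy as np
import pytest
from hypothesis import settings

from imfscan.dataio import GenotypeMatrix, SampleCovariates
from imfscan.synthio import (
    SimulationConfig,
    simulate_covariates,
    simulate_expression,
    simulate_genotypes,
    simulate_trait,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def cohort(default_config):
    """One fully simulated in-memory cohort shared across tests."""
    geno = simulate_genotypes(default_config)
    cov = simulate_covariates(default_config)
    expr = simulate_expression(geno, cov, default_config)
    cov_t = simulate_trait(expr, cov, default_config)
    return {"config": default_config, "geno": geno, "expr": expr, "cov": cov_t}


@pytest.fixture()
def small_covariates() -> SampleCovariates:
    rng = np.random.default_rng(11)
    n = 40
    return SampleCovariates(
        sample_ids=[f"S{i:03d}" for i in range(n)],
        sex=np.asarray(rng.choice(["M", "F"], n), dtype=object),
        batch=np.asarray(rng.choice(["B1", "B2", "B3"], n), dtype=object),
        carcass_weight=rng.normal(100, 8, n),
        trait=rng.normal(5, 2, n),
    )


def toy_genotypes(dosage, chrom=None, pos=None, snp_ids=None) -> GenotypeMatrix:
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    return GenotypeMatrix(
        sample_ids=[f"S{i}" for i in range(n)],
        snp_ids=snp_ids or [f"snp{j}" for j in range(m)],
        chrom=np.asarray(chrom if chrom is not None else ["1"] * m, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, m + 1) * 1000),
        dosage=dosage,
    )
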