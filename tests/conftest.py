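import numpy as np
import pytest

from cismr import (
    LDMatrix,
    MarginalGWAS,
    SummarySimConfig,
    marginal_to_conditional,
    simulate_summary,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def ld2():
    """Two SNPs with correlation 0.5."""
    return LDMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]), ["rs1", "rs2"])


@pytest.fixture
def small_region(rng):
    """A moderate-LD 5-SNP region with one pleiotropic SNP and theta=0.1."""
    cfg = SummarySimConfig.scenario1(
        m=5, k1=1, theta=0.1, n_x=20_000, n_y=50_000
    )
    expo, outc, ld, truth = simulate_summary(cfg, rng=rng)
    return expo, outc, ld, truth, cfg


@pytest.fixture
def small_conditional(small_region):
    expo, outc, ld, truth, cfg = small_region
    return (
        marginal_to_conditional(expo, ld),
        marginal_to_conditional(outc, ld),
        truth,
        cfg,
    )


def random_marginal_pair(rng, m=6, rho=0.4):
    """A random harmonized (exposure, outcome, ld) triple for identity checks."""
    from cismr import ar_ld_matrix

    ld = ar_ld_matrix(m, rho)
    ids = ld.snp_ids
    expo = MarginalGWAS(
        ids, rng.normal(0, 0.2, m), rng.uniform(0.01, 0.05, m), 10_000
    )
    outc = MarginalGWAS(
        ids, rng.normal(0, 0.2, m), rng.uniform(0.01, 0.05, m), 20_000
    )
    return expo, outc, ld
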