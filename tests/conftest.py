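import numpy as np
import pandas as pd
import pytest

from trimeqtl.preprocess import beta_to_m
from trimeqtl.synthetic_data import SimulationConfig, simulate_triads


def m_matrix(betas: pd.DataFrame) -> pd.DataFrame:
    """Samples x CpGs M-value matrix from a beta matrix."""
    return pd.DataFrame(beta_to_m(betas.to_numpy()), index=betas.index, columns=betas.columns)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_study():
    """Five GMeE_GE triads with LD and CpG partners at default effects."""
    cfg = SimulationConfig(n_triads=5, seed=42, n_ld_partners=4, n_cpg_partners=2)
    return simulate_triads(cfg)


@pytest.fixture
def features_toy(rng):
    """Random toy SNP/CpG layout on two chromosomes for cis-pair tests."""
    n_snp, n_cpg = 50, 10
    snps = pd.DataFrame({
        "id": [f"s{i}" for i in range(n_snp)],
        "chrom": rng.choice(["1", "2"], n_snp),
        "pos": rng.integers(1, 5_000_000, n_snp),
    })
    cpgs = pd.DataFrame({
        "id": [f"c{i}" for i in range(n_cpg)],
        "chrom": rng.choice(["1", "2"], n_cpg),
        "pos": rng.integers(1, 5_000_000, n_cpg),
    })
    return snps, cpgs
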