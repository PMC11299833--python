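import numpy as np
import pytest

from fedglmm.glmm import CohortData
from fedglmm.simulate import SimConfig, assemble_study


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_family_cohort(n_fam: int, seed: int, p_extra: int = 1) -> CohortData:
    """Small cohort with block-diagonal family relatedness (not via simulator)."""
    from fedglmm.simulate import default_family, pedigree_relationship

    rng = np.random.default_rng(seed)
    A = pedigree_relationship(default_family())
    n = 16 * n_fam
    V = np.kron(np.eye(n_fam), A)
    X = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(p_extra)])
    L = np.linalg.cholesky(V + 1e-8 * np.eye(n))
    eta = X @ rng.normal(0, 0.5, size=X.shape[1]) + 0.5 * (L @ rng.standard_normal(n))
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    ids = np.array([f"s{i}" for i in range(n)])
    return CohortData(sample_ids=ids, y=y, X=X, V=V)


@pytest.fixture(scope="session")
def small_cohort():
    return random_family_cohort(4, seed=7)


@pytest.fixture(scope="session")
def small_study():
    """12 families (192 subjects), 60 SNPs, 3 sites — protocol-scale fixture."""
    return assemble_study(
        SimConfig(n_families=12, n_snps=60, n_sites=3, subsample_to=None, seed=5)
    )


@pytest.fixture(scope="session")
def study_400():
    """25 families (400 subjects), 100 SNPs, 3 sites, 2 covariates."""
    return assemble_study(
        SimConfig(n_families=25, n_snps=100, n_sites=3, subsample_to=None, seed=11)
    )
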