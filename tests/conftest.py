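import numpy as np
import pytest

from gnetlmm import (
    ExpressionData,
    Kinship,
    SimParams,
    realized_relationship,
    simulate_basic,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def small_panel():
    """100 samples x 60 independent common variants plus their RRM."""
    geno = simulate_genotypes(100, 60, seed=101)
    return geno, realized_relationship(geno)


@pytest.fixture(scope="session")
def random_kinship():
    """A well-conditioned non-trivial PSD covariance for N=50."""
    r = np.random.default_rng(7)
    A = r.normal(size=(50, 50))
    return Kinship(A @ A.T / 50 + 0.2 * np.eye(50))


@pytest.fixture(scope="session")
def power_motif():
    """One mediated-trans dataset: SNP A -> gene A; {A, B} -> C; C -> D."""
    return simulate_basic("power", SimParams(n_samples=379), seed=42)


def iid_expression(rng, n, t, chrom="9", start=1):
    """Expression matrix of iid noise genes placed far from all variants."""
    return ExpressionData(
        rng.normal(size=(n, t)),
        [f"g{i}" for i in range(t)],
        [chrom] * t,
        start + np.arange(t),
    )
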