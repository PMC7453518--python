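import numpy as np
import pandas as pd
import pytest

from transgi.sim import GeneSpec, SimConfig, SnpSpec, TransEffect, simulate


def single_gene_config(
    n_samples: int = 2000,
    h2: float = 0.2,
    phi: float = 0.5,
    n_snps: int = 8,
    causal: tuple[str, ...] = ("rs2", "rs5"),
    n_cohorts: int = 1,
    seed: int = 0,
) -> SimConfig:
    """One cis-regulated gene with one trans target probe."""
    snps = [
        SnpSpec(f"rs{i}", "1", 1_000_000 + i * 5_000, 0.3, None)
        for i in range(n_snps)
    ]
    effects = tuple(1.0 for _ in causal)
    genes = [GeneSpec("g1", "1", 1_005_000, 1_015_000, causal, effects, h2)]
    probes = [("p1", "7", 1_000_000)]
    trans = [TransEffect("g1", "p1", phi)] if phi != 0 else []
    return SimConfig(
        n_samples=n_samples,
        snps=snps,
        genes=genes,
        probes=probes,
        trans_effects=trans,
        n_cohorts=n_cohorts,
        seed=seed,
    )


def exact_corr_columns(n: int, corr: np.ndarray, seed: int = 0) -> pd.DataFrame:
    """Columns whose *sample* correlation matrix equals ``corr`` exactly
    (orthonormalized Gaussian basis rotated by the Cholesky factor)."""
    rng = np.random.default_rng(seed)
    k = corr.shape[0]
    x = rng.standard_normal((n, k))
    x -= x.mean(axis=0)
    q, _ = np.linalg.qr(x)
    l = np.linalg.cholesky(corr)
    out = q @ l.T
    return pd.DataFrame(out, columns=[f"v{i + 1}" for i in range(k)])


@pytest.fixture
def small_dataset():
    return simulate(single_gene_config(n_samples=600, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
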