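import numpy as np
import pandas as pd
import pytest

from coexpipe.preprocessing import CountMatrix, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_planted_expression(
    module_sizes=(50, 50),
    loading=0.8,
    n_samples=100,
    n_background=0,
    seed=0,
    loading_spread=0.0,
    gene_loadings_seed=None,
):
    """Gaussian one-factor planted-module expression matrix + truth labels.

    ``loading_spread`` > 0 gives each module gene its own loading drawn
    uniformly around ``loading`` (clipped to (0, 1)), creating replicable hub
    structure; ``gene_loadings_seed`` fixes those loadings independently of
    the sample noise so two cohorts can share them.
    """
    rng = np.random.default_rng(seed)
    lrng = np.random.default_rng(seed if gene_loadings_seed is None else gene_loadings_seed)
    n_genes = sum(module_sizes) + n_background
    labels = np.zeros(n_genes, dtype=int)
    X = rng.normal(size=(n_genes, n_samples))
    pos = 0
    for m, size in enumerate(module_sizes, start=1):
        eig = rng.normal(size=n_samples)
        lo = np.clip(
            lrng.uniform(loading - loading_spread, loading + loading_spread, size=size),
            0.05, 0.99,
        )
        X[pos : pos + size] = (
            lo[:, None] * eig + np.sqrt(1 - lo**2)[:, None] * X[pos : pos + size]
        )
        labels[pos : pos + size] = m
        pos += size
    genes = pd.Index([f"g{i:04d}" for i in range(n_genes)], name="gene")
    df = pd.DataFrame(X, index=genes, columns=[f"s{j:03d}" for j in range(n_samples)])
    return df, pd.Series(labels, index=genes)


@pytest.fixture
def planted_two_blocks():
    return make_planted_expression(module_sizes=(50, 50), loading=0.95, n_samples=120, seed=7)


@pytest.fixture
def small_counts(rng):
    counts = rng.negative_binomial(5, 0.1, size=(40, 6))
    return CountMatrix(
        counts=pd.DataFrame(
            counts,
            index=[f"g{i}" for i in range(40)],
            columns=[f"s{j}" for j in range(6)],
        )
    )


@pytest.fixture
def gaussian_expr(rng):
    vals = rng.normal(8.0, 2.0, size=(30, 12))
    return ExpressionMatrix(
        values=pd.DataFrame(
            vals,
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(12)],
        ),
        unit="log-intensity",
    )
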