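import numpy as np
import pandas as pd
import pytest

from eggimmune.de import CountMatrix


def make_count_matrix(counts: np.ndarray, treatments=None, genotypes=None,
                      gene_ids=None) -> CountMatrix:
    """CountMatrix from a raw array with a minimal two-condition design."""
    n_genes, n_samples = counts.shape
    if treatments is None:
        half = n_samples // 2
        treatments = ["naive"] * half + ["septic"] * (n_samples - half)
    if genotypes is None:
        genotypes = ["wildtype"] * n_samples
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    sample_ids = [f"s{j}" for j in range(n_samples)]
    design = pd.DataFrame(
        {"genotype": genotypes, "treatment": treatments,
         "replicate": list(range(1, n_samples + 1))},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        design=design,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def nb_counts_3v3(rng):
    """1000 null NB genes (alpha=0.05), 3 vs 3 design, plus the truth."""
    n = 1000
    alpha = 0.05
    mu = 10 ** rng.uniform(1, 3, n)
    lam = rng.gamma(1 / alpha, alpha * mu[:, None], size=(n, 6))
    counts = rng.poisson(lam)
    return make_count_matrix(counts), mu, alpha
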