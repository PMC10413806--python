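import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import burstkit as bk

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_matrix():
    """Deterministic 30-gene x 120-cell simulated count matrix with truth."""
    rng = np.random.default_rng(1234)
    n_genes, n_cells = 30, 120
    kon = np.exp(rng.uniform(np.log(0.1), np.log(2), n_genes))
    koff = np.exp(rng.uniform(np.log(1), np.log(10), n_genes))
    ksyn = np.exp(rng.uniform(np.log(10), np.log(80), n_genes))
    counts = np.vstack(
        [
            bk.sample_poisson_beta(bk.BurstParams(kon[i], koff[i], ksyn[i]), n_cells, rng=rng)
            for i in range(n_genes)
        ]
    )
    matrix = bk.UmiCountMatrix(
        pd.DataFrame(
            counts,
            index=[f"gene_{i}" for i in range(n_genes)],
            columns=[f"cell_{j}" for j in range(n_cells)],
        )
    )
    truth = pd.DataFrame(
        {"gene_id": matrix.gene_ids, "k_on": kon, "k_off": koff, "k_syn": ksyn}
    )
    return matrix, truth


@pytest.fixture(scope="session")
def toy_genome():
    """Small TAD genome: 4 TADs x 3 genes, 2 boundary genes per boundary."""
    return bk.simulate_genome(
        n_tads=4, genes_per_tad=3, boundary_genes_per_boundary=2, seed=7
    )
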