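import numpy as np
import pandas as pd
import pytest
import anndata as ad

import screg


@pytest.fixture(scope="session")
def small_config():
    return screg.SimConfig(
        n_genes=300, n_regulators=8, targets_per_regulator=12,
        n_cells_per_condition=150, marker_genes_per_type=12, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return screg.simulate_dataset(small_config)


def make_counts(matrix, conditions=None, gene_names=None):
    """Tiny dense AnnData helper for hand-built examples (cells x genes)."""
    X = np.asarray(matrix)
    n, g = X.shape
    obs = pd.DataFrame(index=[f"cell{i}" for i in range(n)])
    if conditions is not None:
        obs["condition"] = conditions
    genes = gene_names or [f"g{j}" for j in range(g)]
    return ad.AnnData(X=X.astype(np.int64),
                      obs=obs, var=pd.DataFrame(index=genes))
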