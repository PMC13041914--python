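import anndata as ad
import numpy as np
import pandas as pd
import pytest

from rrgkit import matrixops, synthdata


@pytest.fixture(scope="session")
def small_sim():
    """A small two-condition simulation with planted effect, shared across tests."""
    cfg = synthdata.SimConfig(
        n_cells=600,
        n_genes=400,
        n_responsive=60,
        frac_erpos=0.5,
        conditions=("vehicle", "E2"),
        timepoints=("4h",),
        effect_log2fc=1.5,
        seed=42,
    )
    adata, truth = synthdata.generate_counts(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def small_norm(small_sim):
    _, adata, _ = small_sim
    return matrixops.lognormalize(adata)


def toy_adata(matrix, gene_names=None, cell_names=None, **var_cols):
    """Dense toy AnnData builder for hand-computed examples."""
    X = np.asarray(matrix, dtype=float)
    n_obs, n_var = X.shape
    var = pd.DataFrame(index=pd.Index(gene_names or [f"g{i}" for i in range(n_var)], name="symbol"))
    for k, v in var_cols.items():
        var[k] = v
    obs = pd.DataFrame(index=pd.Index(cell_names or [f"c{i}" for i in range(n_obs)], name="barcode"))
    return ad.AnnData(X=X, obs=obs, var=var)
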