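import anndata as ad
import numpy as np
import pandas as pd
import pytest

from icbmm.synthetic_data import SimConfig, generate_sc_dataset


@pytest.fixture(scope="session")
def small_sim():
    """One small generated single-cell dataset shared across tests."""
    cfg = SimConfig(seed=11, n_cells=1200, n_genes=500)
    adata, records, truth = generate_sc_dataset(cfg)
    return cfg, adata, records, truth


@pytest.fixture()
def toy_adata():
    """Hand-built 6-cell x 8-gene dataset for boundary QC tests."""
    genes = [f"g{i}" for i in range(6)] + ["MT-a", "MT-b"]
    X = np.array([
        [5, 4, 3, 2, 1, 1, 0, 0],   # fine immune cell
        [5, 4, 3, 2, 1, 1, 2, 0],   # 2/18 = 11% mito -> fails immune 6% rule
        [9, 0, 0, 0, 0, 0, 1, 0],   # 10% mito but CD45neg -> passes 20% rule
        [0, 0, 1, 0, 0, 0, 0, 0],   # 1 detected gene -> fails min_genes=2
        [6, 5, 4, 3, 2, 1, 0, 0],   # fine immune cell
        [2, 2, 2, 0, 0, 0, 0, 0],   # fine immune cell
    ])
    obs = pd.DataFrame(
        {"fraction": ["CD45pos", "CD45pos", "CD45neg", "CD45pos",
                      "CD45pos", "CD45pos"]},
        index=pd.Index([f"c{i}" for i in range(6)], name="cell_id"))
    var = pd.DataFrame({"mito": [g.startswith("MT-") for g in genes]},
                       index=pd.Index(genes, name="gene_id"))
    return ad.AnnData(X=X, obs=obs, var=var)
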