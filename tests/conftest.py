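import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from rejuvseq.qc import normalize
from rejuvseq.simulate import SimConfig, simulate


def make_adata(dense, genes=None, barcodes=None, obs=None):
    """Build an AnnData from a dense genes x cells array (matrix orientation
    as on disk; transposed internally to cells x genes)."""
    dense = np.asarray(dense, dtype=float)
    n_genes, n_cells = dense.shape
    genes = list(genes) if genes is not None else [f"g{i}" for i in range(n_genes)]
    barcodes = (
        list(barcodes) if barcodes is not None else [f"c{i}" for i in range(n_cells)]
    )
    adata = ad.AnnData(
        X=sp.csr_matrix(dense.T),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    if obs:
        for k, v in obs.items():
            adata.obs[k] = v
    return adata


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete four-arm simulation shared across tests."""
    cfg = SimConfig(
        n_genes=400,
        cell_types=(("Hep", 80),),
        n_planted_up=40,
        n_planted_down=40,
        seed=7,
    )
    adata, truth = simulate(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def small_norm(small_sim):
    _, adata, _ = small_sim
    return normalize(adata)
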