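import anndata as ad
import numpy as np
import pandas as pd
import pytest

from binsig import synth


def make_adata(values, genes=None, cells=None, layer="raw_counts", obs=None):
    """Small AnnData from a genes x cells array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    genes = genes or [f"G{i}" for i in range(n_genes)]
    cells = cells or [f"C{j}" for j in range(n_cells)]
    adata = ad.AnnData(
        X=values.T,
        obs=obs if obs is not None else pd.DataFrame(index=pd.Index(cells, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
    if obs is not None:
        adata.obs.index = pd.Index(cells, name="cell_id")
    adata.uns["layer"] = layer
    adata.var["is_spikein"] = adata.var_names.str.startswith("ERCC-")
    return adata


@pytest.fixture
def small_config():
    return synth.SynthConfig(seed=7, n_cells_per_group=50, n_genes=300)


@pytest.fixture
def sc_dataset(small_config):
    return synth.make_sc_dataset(small_config)


@pytest.fixture
def atlas_bundle(small_config):
    return synth.make_atlas(small_config)


@pytest.fixture
def repertoire_bundle(small_config):
    return synth.make_repertoire(small_config)
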