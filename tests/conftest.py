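import numpy as np
import pandas as pd
import pytest

from markercov import SimConfig, generate_counts, make_anndata


@pytest.fixture(scope="session")
def small_sim():
    """3 unequal clusters, planted markers, contaminants; session-cached."""
    cfg = SimConfig(
        n_clusters=3,
        cells_per_cluster=[80, 120, 100],
        n_genes=300,
        n_marker_genes_per_cluster=5,
        marker_fold_change=8.0,
        baseline_mean=1.0,
        dispersion=0.5,
        frac_mito_genes=0.05,
        frac_hemoglobin_genes=0.02,
        n_low_quality_cells=10,
        n_doublets=5,
        seed=7,
    )
    return generate_counts(cfg)


@pytest.fixture()
def toy_adata():
    """Hand-written 6-gene × 5-cell matrix (genes × cells on input)."""
    counts = np.array(
        [
            [5, 0, 3, 2, 1],
            [0, 1, 0, 4, 2],
            [1, 2, 3, 0, 0],
            [0, 0, 0, 1, 0],
            [2, 2, 2, 2, 2],
            [0, 0, 1, 0, 0],
        ]
    )
    genes = ["G1", "G2", "G3", "MT-1", "G4", "HB1"]
    cells = [f"c{i}" for i in range(1, 6)]
    return make_anndata(counts, genes, cells)


def labels_series(adata, values):
    return pd.Series(list(values), index=adata.obs_names, name="label")
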