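import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from allosc import CountMatrix, NormalizedMatrix, SynthConfig, normalize
from allosc.synth import simulate_counts, simulate_study


def make_count_matrix(values, symbols=None, biotype=None, **meta):
    """Build a small CountMatrix from a dense genes x cells array."""
    values = np.asarray(values)
    n_genes, n_cells = values.shape
    symbols = symbols or [f"G{i}" for i in range(n_genes)]
    genes = pd.DataFrame(
        {
            "symbol": symbols,
            "biotype": biotype or ["protein_coding"] * n_genes,
            "length": np.linspace(500, 5000, n_genes).astype(int),
        },
        index=pd.Index([f"g{i:03d}" for i in range(n_genes)], name="gene_id"),
    )
    defaults = dict(sample_id="s0", patient="P0", timepoint="pre", stimulus="don", chip="c0")
    defaults.update(meta)
    cell_meta = pd.DataFrame(
        {k: [v] * n_cells if np.isscalar(v) or isinstance(v, str) else v
         for k, v in defaults.items()},
        index=pd.Index([f"cell{i:03d}" for i in range(n_cells)], name="barcode"),
    )
    return CountMatrix(values=sp.csr_matrix(values), genes=genes, cell_meta=cell_meta)


def make_normalized(values, **meta):
    """NormalizedMatrix whose values are ln(1+x) of the given dense array."""
    m = make_count_matrix(values, **meta)
    return normalize(m)


@pytest.fixture(scope="session")
def small_study():
    """A compact two-patient synthetic study reused by several suites."""
    cfg = SynthConfig(rng_seed=11, n_patients=2, include_thirdparty=False)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def clean_counts():
    """Small clean expression data: no doublets, dead cells or contaminant."""
    cfg = SynthConfig(
        rng_seed=5, n_patients=1, include_thirdparty=False, n_genes=800,
        n_clusters=3, contaminant_cluster=False, marker_genes_per_cluster=15,
        doublet_rate=0.0, dead_cell_rate=0.0, prepost_gene_count=0,
    )
    return simulate_counts(cfg)
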