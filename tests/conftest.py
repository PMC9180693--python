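import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scortho.io_formats import CountMatrix
from scortho.synthetic_data import SimParams, simulate_paired_experiment


def make_counts(array, gene_ids=None, barcodes=None, meta=None) -> CountMatrix:
    arr = np.asarray(array)
    n_genes, n_cells = arr.shape
    gene_ids = gene_ids or [f"G{i}" for i in range(n_genes)]
    barcodes = barcodes or [f"BC{i}" for i in range(n_cells)]
    if meta is None:
        meta = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    return CountMatrix(
        counts=sp.csr_matrix(arr), gene_ids=gene_ids, barcodes=barcodes, cell_meta=meta
    )


@pytest.fixture
def tiny_counts() -> CountMatrix:
    meta = pd.DataFrame(
        {
            "species": ["speciesA", "speciesA"],
            "condition": ["case", "control"],
            "sample": ["s1", "s1"],
        },
        index=pd.Index(["BC0", "BC1"], name="barcode"),
    )
    return make_counts([[1, 0], [0, 2], [3, 4]], meta=meta)


SMALL_PARAMS = SimParams(
    n_types=4,
    cells_per_type_per_species_per_condition=80,
    n_pairs_one2one=300,
    n_pairs_one2many=10,
    n_unique_genes_per_species=40,
    marker_genes_per_type=10,
    n_de_per_type=20,
    seed=0,
)


@pytest.fixture(scope="session")
def small_sim():
    """A reduced-scale paired experiment shared across tests."""
    return simulate_paired_experiment(SMALL_PARAMS)
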