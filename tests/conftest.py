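import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from adaptscales.io import CountMatrix, QCThresholds


def make_count_matrix(counts, cell_meta=None, sample_ids=None):
    """CountMatrix from a dense array with generated ids."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    cell_ids = np.array([f"c{i}" for i in range(n_cells)], dtype=object)
    gene_ids = np.array([f"g{j}" for j in range(n_genes)], dtype=object)
    if cell_meta is None:
        cell_meta = pd.DataFrame(
            {"sample_id": sample_ids or ["s0"] * n_cells}, index=cell_ids
        )
    return CountMatrix(sp.csr_matrix(counts), cell_ids, gene_ids, cell_meta)


# Hand-built QC fixture: 6 cells x 12 genes.  With thresholds
# min_genes=3, max_genes=6, min_counts=10, min_cells_per_gene=2, rule-by-rule
# hand application retains cells (c0, c4, c5) and genes g0..g6 -> shape (3, 7):
#   c0: 4 expressed genes, 10 total  -> kept (both at the inclusive boundary)
#   c1: 7 expressed genes            -> removed (> max_genes)
#   c2: 2 expressed genes            -> removed (< min_genes)
#   c3: 9 total counts               -> removed (< min_counts)
#   c4: 6 expressed genes, 12 total  -> kept (max_genes boundary)
#   c5: 5 expressed genes, 13 total  -> kept
# then genes expressed in >= 2 of the kept cells: g0,g1,g2 (c0,c4),
# g3 (c0,c5), g4,g5,g6 (c4,c5); g7 appears only in c5, g8..g11 nowhere.
QC_FIXTURE = np.array(
    [
        [3, 3, 2, 2, 0, 0, 0, 0, 0, 0, 0, 0],
        [2, 2, 2, 2, 2, 2, 2, 0, 0, 0, 0, 0],
        [5, 5, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [2, 2, 2, 2, 1, 0, 0, 0, 0, 0, 0, 0],
        [2, 2, 2, 0, 2, 2, 2, 0, 0, 0, 0, 0],
        [0, 0, 0, 3, 3, 3, 2, 2, 0, 0, 0, 0],
    ]
)
QC_FIXTURE_THRESHOLDS = QCThresholds(
    min_genes=3, max_genes=6, min_counts=10, min_cells_per_gene=2
)
QC_FIXTURE_EXPECTED_SHAPE = (3, 7)
QC_FIXTURE_EXPECTED_CELLS = ["c0", "c4", "c5"]
QC_FIXTURE_EXPECTED_GENES = ["g0", "g1", "g2", "g3", "g4", "g5", "g6"]


@pytest.fixture
def qc_fixture_matrix():
    return make_count_matrix(QC_FIXTURE)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
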