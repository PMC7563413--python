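import numpy as np
import pytest
import scipy.sparse as sp

from navsig import CountMatrix, NormalizedMatrix, SimConfig


@pytest.fixture
def tiny_counts():
    """4 cells x 5 genes with one mitochondrial gene and known totals."""
    counts = np.array([
        [5, 0, 3, 2, 0],    # total 10
        [0, 0, 0, 0, 0],    # empty cell
        [10, 10, 10, 10, 10],
        [1, 2, 3, 4, 0],
    ])
    return CountMatrix(cells=[f"c{i}" for i in range(4)],
                       genes=["A", "B", "C", "D", "MT-1"],
                       counts=sp.csr_matrix(counts))


@pytest.fixture
def small_sim_config():
    """Down-scaled simulation reused across tests (fast, planted effect)."""
    return SimConfig(n_cells=600, n_genes=800, phase_set_size=40,
                     resistance_set_size=30, target_set_size=30,
                     fraction_resistant=0.3, fraction_sensitive=0.3,
                     effect_log2=1.0, seed=11)


def dense_norm(values, cells=None, genes=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return NormalizedMatrix(
        cells=cells or [f"c{i}" for i in range(n)],
        genes=genes or [f"g{j}" for j in range(m)],
        values=values)
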