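import numpy as np
import pytest
import scipy.sparse as sp

from plaquemap.io_formats import ClusterAssignment, CountMatrix
from plaquemap.synthetic_data import Population, SimulationDesign, simulate_counts


@pytest.fixture
def random_counts():
    """50 genes × 30 cells of sparse random counts (seed 1)."""
    rng = np.random.default_rng(1)
    dense = rng.poisson(0.8, size=(50, 30))
    genes = [f"G{i:03d}" for i in range(50)]
    barcodes = [f"cell{i:03d}" for i in range(30)]
    return CountMatrix(genes, barcodes, sp.csr_matrix(dense))


@pytest.fixture
def three_clusters(random_counts):
    labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
    return ClusterAssignment(dict(zip(random_counts.barcodes, labels)))


@pytest.fixture(scope="session")
def small_simulation():
    """5 populations × 50 cells, 20 planted markers each, fold 4."""
    pops = [
        Population(f"P{j}", 50, list(range(j * 20, (j + 1) * 20)), 4.0)
        for j in range(5)
    ]
    design = SimulationDesign(n_genes=600, populations=pops, dispersion=0.5, seed=11)
    return simulate_counts(design)
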