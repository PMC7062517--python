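from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from dropchim import CountMatrix, SimConfig, simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """300 cells + 1,000 ambient droplets, bimodal library sizes."""
    cfg = SimConfig(
        n_cells=300,
        chimerism_fraction=0.7,
        n_ambient_droplets=1000,
        mean_cell_umis=1000.0,
        mean_ambient_umis=10.0,
        library_sigma=0.25,
        seed=42,
    )
    matrix, truth = simulate_counts(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def cells_only_sim():
    cfg = SimConfig(n_cells=400, chimerism_fraction=0.7, seed=7)
    matrix, truth = simulate_counts(cfg)
    return cfg, matrix, truth


def make_matrix(counts: np.ndarray, genes=None, barcodes=None) -> CountMatrix:
    """Dense genes x barcodes array -> CountMatrix with default identifiers."""
    counts = np.asarray(counts)
    genes = genes or [f"G{i}" for i in range(counts.shape[0])]
    barcodes = barcodes or [f"BC{j:04d}" for j in range(counts.shape[1])]
    return CountMatrix(sp.csr_matrix(counts), list(genes), list(barcodes))


@pytest.fixture
def tiny_matrix():
    genes = ["MT-CO1", "XIST", "CD68", "RPS2"]
    counts = np.array(
        [
            [2, 0, 1],
            [3, 0, 0],
            [5, 0, 2],
            [0, 0, 7],
        ]
    )
    return make_matrix(counts, genes=genes)
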