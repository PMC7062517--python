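"""Normalization, PCA embedding and modularity clustering.

Counts are library-size log-normalized, embedded by gene-centered SVD, and
cells are clustered by greedy modularity maximization on a k-nearest-neighbor
graph built from Euclidean distances in principal-component space.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .types import CountMatrix

NORMALIZE_SCALE = 10_000.0
DEFAULT_N_COMPONENTS = 10
DEFAULT_K_NEIGHBORS = 15


@dataclass
class Embedding:
    coords: np.ndarray  # cells x components
    variance_shares: np.ndarray  # share of total variance, non-increasing
    n_components: int


@dataclass
class ClusterLabels:
    labels: np.ndarray  # per-cell community, contiguous from 0
    modularity: float


def normalize_log(matrix: CountMatrix, scale: float = NORMALIZE_SCALE) -> sp.csr_matrix:
    """ln(1 + scale * count / library_size); preserves the zero pattern."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    lib = matrix.library_sizes().astype(float)
    if (lib == 0).any():
        raise ValueError("zero library size; run QC before normalization")
    x = matrix.matrix.tocsc().astype(float)
    x = x.multiply(scale / lib[np.newaxis, :]).tocsr()
    x.data = np.log1p(x.data)
    return x


def pca_embed(matrix, n_components: int) -> Embedding:
    """Gene-centered SVD embedding of cells.

    Accepts a genes x cells matrix (sparse or dense). Component signs are
    fixed by forcing the largest-magnitude gene loading of each component
    positive, making the embedding bit-reproducible.
    """
    x = matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix, dtype=float)
    cells = x.T  # cells x genes
    n_cells, n_genes = cells.shape
    if n_components > min(n_cells, n_genes):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_cells, n_genes)={min(n_cells, n_genes)}"
        )
    centered = cells - cells.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest |loading| positive per component
    for j in range(len(s)):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    total_var = float((s**2).sum())
    shares = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    coords = u[:, :n_components] * s[:n_components]
    return Embedding(coords=coords, variance_shares=shares, n_components=n_components)


def knn_graph(coords: np.ndarray, k_neighbors: int) -> nx.Graph:
    """Undirected union of each cell's k nearest Euclidean neighbors."""
    n = coords.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in idx[i, 1:]:
            g.add_edge(i, int(j))
    return g


def cluster_modularity(
    embedding: Embedding | np.ndarray, k_neighbors: int = DEFAULT_K_NEIGHBORS
) -> ClusterLabels:
    """Greedy modularity communities on the kNN graph of the embedding.

    Communities are relabeled by their lowest member index so labels are
    contiguous from 0 and permutation-equivariant up to relabeling.
    """
    coords = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding)
    g = knn_graph(coords, k_neighbors)
    communities = nx.community.greedy_modularity_communities(g)
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    labels = np.empty(coords.shape[0], dtype=int)
    for lab, members in enumerate(communities):
        labels[members] = lab
    q = nx.community.modularity(g, [set(c) for c in communities])
    return ClusterLabels(labels=labels, modularity=float(q))
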