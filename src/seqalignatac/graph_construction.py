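"""kNN cell-graph construction and GCN adjacency normalization.

Each domain (reference or query) becomes a graph whose nodes are cells,
whose features are the cell embeddings, and whose edges connect each cell to
its k nearest neighbors in embedding space (symmetrized by union). The
normalized adjacency is the standard self-looped symmetric GCN operator
A_hat = D^{-1/2} (A + I) D^{-1/2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from .sequence_embedding import CellEmbeddingMatrix

_METRICS = ("euclidean", "cosine")


@dataclass
class DomainGraph:
    node_ids: list[str]
    features: np.ndarray
    edges: set  # ordered pairs (i, j), i != j, symmetric after construction
    k: int
    metric: str
    normalized_adjacency: sp.csr_matrix = field(default=None)

    @property
    def n_nodes(self):
        return len(self.node_ids)


def build_knn_graph(emb: CellEmbeddingMatrix, k: int,
                    metric: str = "euclidean") -> DomainGraph:
    """Exact kNN graph with deterministic (distance, index) tie-breaking.

    Directed edges to the k nearest distinct neighbors are symmetrized by
    union. The normalized adjacency is computed immediately.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    x = np.asarray(emb.values, dtype=np.float64)
    n = x.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k={k} must satisfy 1 <= k < n_cells={n}")
    if len(set(emb.cell_ids)) != n:
        raise ValueError("duplicate cell_ids in embedding")
    if not np.isfinite(x).all():
        raise ValueError("embedding features must be finite")
    if metric == "cosine" and (np.linalg.norm(x, axis=1) == 0).any():
        raise ValueError("cosine metric undefined for zero-norm embeddings")

    dist = cdist(x, x, metric=metric)
    np.fill_diagonal(dist, np.inf)
    # stable argsort breaks distance ties by ascending node index
    nbrs = np.argsort(dist, axis=1, kind="stable")[:, :k]
    edges = set()
    for i in range(n):
        for j in nbrs[i]:
            edges.add((i, int(j)))
            edges.add((int(j), i))
    g = DomainGraph(list(emb.cell_ids), x, edges, k, metric)
    normalize_adjacency(g)
    return g


def normalize_adjacency(g: DomainGraph) -> sp.csr_matrix:
    """Set g.normalized_adjacency = D^{-1/2} (A + I) D^{-1/2} and return it."""
    n = g.n_nodes
    if g.edges:
        rows, cols = zip(*g.edges)
        a = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    else:
        a = sp.coo_matrix((n, n))
    a_tilde = (a + sp.eye(n)).tocsr()
    deg = np.asarray(a_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    g.normalized_adjacency = (d_inv_sqrt @ a_tilde @ d_inv_sqrt).tocsr()
    return g.normalized_adjacency


def write_edge_list(g: DomainGraph, path):
    with open(path, "w") as fh:
        for i, j in sorted(g.edges):
            fh.write(f"{i}\t{j}\n")
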