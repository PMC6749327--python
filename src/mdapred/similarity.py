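"""miRNA functional similarity, kNN neighbour graph and graph Laplacian.

The smoothness penalty Tr(U^T L U) used by the model assumes miRNAs with
similar disease profiles should receive similar association scores; the
Laplacian L = W - S is built from a k-nearest-neighbour graph S over the
miRNA similarity matrix, with W the diagonal degree matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AssociationMatrix, SimilarityMatrix

__all__ = [
    "NeighborGraph",
    "LaplacianPair",
    "mirna_functional_similarity",
    "build_neighbor_graph",
    "graph_laplacian",
    "write_edge_list",
]


@dataclass
class NeighborGraph:
    """Binary kNN graph S over miRNAs. S[i, j] = 1 when miRNA i is one of
    the k most similar neighbours of miRNA j (diagonal excluded)."""

    S: np.ndarray
    k: int
    symmetrized: bool

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = self.S.shape[0]
        if self.S.shape != (n, n):
            raise ValueError("neighbour graph must be square")
        if np.diagonal(self.S).any():
            raise ValueError("neighbour graph diagonal must be zero")


@dataclass
class LaplacianPair:
    """Degree matrix W (diagonal, W_ii = sum_j S_ij) and Laplacian L = W - S."""

    W: np.ndarray
    L: np.ndarray


def mirna_functional_similarity(A: AssociationMatrix,
                                D: SimilarityMatrix) -> SimilarityMatrix:
    """Functional similarity between miRNAs from their associated disease sets.

    Best-match averaging: with Sa, Sb the disease sets of miRNAs a and b,

        Sim(a, b) = [ sum_{d in Sa} max_{d' in Sb} D(d, d')
                    + sum_{d in Sb} max_{d' in Sa} D(d, d') ] / (|Sa| + |Sb|)

    Sim(a, a) = 1 for a miRNA with at least one associated disease; any
    similarity involving an empty disease set is 0.
    """
    if A.disease_ids != D.ids:
        raise ValueError("disease similarity must cover the diseases of A "
                         "in the same order (align first)")
    Ab = A.values > 0.5
    nm = A.n_mirna
    Dv = D.values
    sizes = Ab.sum(axis=1)
    # best[b, d] = max over d' in Sb of D(d, d'); zero row for empty Sb
    best = np.zeros((nm, A.n_disease))
    for b in range(nm):
        if sizes[b]:
            best[b] = Dv[:, Ab[b]].max(axis=1)
    # cross[a, b] = sum_{d in Sa} best[b, d]
    cross = Ab.astype(float) @ best.T
    denom = sizes[:, None] + sizes[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, (cross + cross.T) / np.maximum(denom, 1), 0.0)
    empty = sizes == 0
    sim[empty, :] = 0.0
    sim[:, empty] = 0.0
    np.fill_diagonal(sim, np.where(empty, 0.0, 1.0))
    return SimilarityMatrix(np.maximum(sim, 0.0), A.mirna_ids, "mirna")


def build_neighbor_graph(M: SimilarityMatrix | np.ndarray, k: int,
                         symmetrize: bool = True) -> NeighborGraph:
    """Binary kNN graph from a miRNA similarity matrix.

    Row i marks miRNA i's neighbours: the ``min(k, # strictly positive
    candidates)`` columns j with the largest M[i, j] (j != i) receive
    S[i, j] = 1, ties broken by the smaller column index, so each row's
    degree W_ii counts i's own neighbours.  With ``symmetrize`` the result
    is the elementwise max of the raw graph and its transpose.
    """
    Mv = M.values if isinstance(M, SimilarityMatrix) else np.asarray(M, float)
    n = Mv.shape[0]
    if k <= 0:
        raise ValueError("k must be a positive integer")
    if k >= n:
        raise ValueError(f"k={k} must be < number of miRNAs ({n})")
    S = np.zeros((n, n))
    for i in range(n):
        row = Mv[i].copy()
        row[i] = -np.inf
        order = np.argsort(-row, kind="stable")  # ties -> smaller index first
        order = order[row[order] > 0]
        S[i, order[:k]] = 1.0
    if symmetrize:
        S = np.maximum(S, S.T)
    return NeighborGraph(S=S, k=k, symmetrized=symmetrize)


def graph_laplacian(G: NeighborGraph) -> LaplacianPair:
    """Degree matrix and combinatorial Laplacian L = W - S of the graph."""
    degrees = G.S.sum(axis=1)
    W = np.diag(degrees)
    return LaplacianPair(W=W, L=W - G.S)


def write_edge_list(G: NeighborGraph, path: str | Path) -> None:
    """Export the graph as a three-column (i, j, 1) TSV for inspection."""
    i, j = np.nonzero(G.S)
    pd.DataFrame({"i": i, "j": j, "w": np.ones(len(i), dtype=int)}).to_csv(
        path, sep="\t", header=False, index=False)
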