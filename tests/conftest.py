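"""Shared fixtures: small random model instances with strictly positive factors."""

import numpy as np
import pytest

from mdapred import Hyperparameters
from mdapred.model import ModelState
from mdapred.similarity import NeighborGraph, build_neighbor_graph, graph_laplacian


def random_instance(seed, nm=4, nd=3, c=2, n_attr=3, k=2, alphas=0.1):
    """Random strictly-positive instance: (state, (A, M, D, C), h)."""
    rng = np.random.default_rng(seed)
    A = (rng.uniform(size=(nm, nd)) < 0.4).astype(float)
    M = rng.uniform(0.1, 1.0, size=(nm, nm))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 1.0)
    D = rng.uniform(0.1, 0.9, size=(nd, nd))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 1.0)
    C = (rng.uniform(size=(nm, n_attr)) < 0.5).astype(float)
    graph = build_neighbor_graph(M, k=k, symmetrize=True)
    lap = graph_laplacian(graph)
    state = ModelState(
        U=rng.uniform(0.1, 1.0, size=(nm, nd)),
        X=rng.uniform(0.1, 1.0, size=(nm, c)),
        Y=rng.uniform(0.1, 1.0, size=(nd, c)),
        Z=rng.uniform(0.1, 1.0, size=(n_attr, c)),
        S=graph.S, W=lap.W, L=lap.L,
    )
    if np.isscalar(alphas):
        alphas = (alphas,) * 4
    h = Hyperparameters(alpha1=alphas[0], alpha2=alphas[1], alpha3=alphas[2],
                        alpha4=alphas[3], c=c, k_neighbors=k, seed=seed)
    return state, (A, M, D, C), h


def scalar_instance(A=1.0, U=0.5, M=1.0, D=1.0, C=1.0, X=1.0, Y=1.0, Z=1.0,
                    **hkw):
    """All-dims-1 instance for hand-evaluated update examples (no graph)."""
    one = lambda v: np.array([[float(v)]])
    state = ModelState(U=one(U), X=one(X), Y=one(Y), Z=one(Z),
                       S=np.zeros((1, 1)), W=np.zeros((1, 1)),
                       L=np.zeros((1, 1)))
    hkw.setdefault("c", 1)
    hkw.setdefault("k_neighbors", 1)
    h = Hyperparameters(**hkw)
    return state, (one(A), one(M), one(D), one(C)), h


@pytest.fixture
def tiny_synthetic():
    """A small planted dataset used across fit-level tests."""
    from mdapred import SyntheticConfig, generate
    cfg = SyntheticConfig(n_mirna=40, n_disease=15, n_family=8, n_cluster=10,
                          rank=4, density=0.1, flip_prob=0.05, seed=0)
    return generate(cfg)
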