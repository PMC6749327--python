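"""Graph-regularized nonnegative matrix factorization for association scoring.

The score matrix U (miRNA x disease) is estimated by minimising

    L(U, X, Y, Z) = ||U - A||_F^2
                  + a1 ||U - M X (D Y)^T||_F^2
                  + a2 ||U - C Z (D Y)^T||_F^2
                  + a3 Tr(U^T L U)
                  + a4 ||U||_1          subject to U, X, Y, Z >= 0,

where A is the observed binary association matrix, M and D the miRNA and
disease similarity matrices, C the binary family/cluster attribute matrix,
and L the Laplacian of the miRNA kNN graph.  X, Y and Z project the
similarities and node attributes into a shared c-dimensional space, so the
score of a pair is pushed toward the inner product of the miRNA's and the
disease's low-dimensional feature vectors.  The solver cycles four
multiplicative (coordinate-descent) block updates that preserve
nonnegativity exactly.

When the attribute matrix C has zero columns the a2 term is dropped from
the objective and from every update (there is no attribute information to
project), and Z stays an empty (0, c) block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Dataset, Hyperparameters
from .similarity import build_neighbor_graph, graph_laplacian

__all__ = [
    "ObjectiveBreakdown",
    "ModelState",
    "objective",
    "update_U",
    "update_X",
    "update_Y",
    "update_Z",
    "gradients",
    "kkt_residuals",
    "fit",
    "predict_scores",
    "candidate_ranking",
]

# additive floor applied to every multiplicative-update denominator; the
# raw update is undefined where a denominator entry is exactly zero
DENOM_FLOOR = 1e-12


@dataclass
class ObjectiveBreakdown:
    """Componentwise value of the objective at one state."""

    fit_term: float         # ||U - A||_F^2
    similarity_term: float  # ||U - MX(DY)^T||_F^2
    attribute_term: float   # ||U - CZ(DY)^T||_F^2 (0 when C has no columns)
    graph_term: float       # Tr(U^T L U)
    sparsity_term: float    # ||U||_1
    total: float

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.fit_term, self.similarity_term, self.attribute_term,
                self.graph_term, self.sparsity_term, self.total)


@dataclass
class ModelState:
    """Factor set and graph structures of a (partially) fitted model."""

    U: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    S: np.ndarray
    W: np.ndarray
    L: np.ndarray
    objective_trace: list[ObjectiveBreakdown] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    @property
    def objective_totals(self) -> np.ndarray:
        return np.array([b.total for b in self.objective_trace])


def _arrays(data) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(data, Dataset):
        return (data.A.values, data.M.values, data.D.values, data.C.values)
    A, M, D, C = data
    A = np.asarray(A, float)
    if C is None:
        C = np.zeros((A.shape[0], 0))
    return A, np.asarray(M, float), np.asarray(D, float), np.asarray(C, float)


def _check_dims(A, M, D, C, U, X, Y, Z) -> None:
    nm, nd = A.shape
    pairs = [("M", M.shape, (nm, nm)), ("D", D.shape, (nd, nd)),
             ("U", U.shape, (nm, nd))]
    for name, got, want in pairs:
        if got != want:
            raise ValueError(f"dimension mismatch: {name} has shape {got}, "
                             f"expected {want} given A {A.shape}")
    c = X.shape[1]
    if X.shape != (nm, c) or Y.shape != (nd, c) or Z.shape != (C.shape[1], c):
        raise ValueError(
            f"dimension mismatch among factors: X {X.shape}, Y {Y.shape}, "
            f"Z {Z.shape}, C {C.shape}")


def objective(state: ModelState, data, h: Hyperparameters) -> ObjectiveBreakdown:
    """Exact componentwise evaluation of the objective; no mutation."""
    A, M, D, C = _arrays(data)
    return _objective(state.U, state.X, state.Y, state.Z, A, M, D, C,
                      state.L, h)


def _objective(U, X, Y, Z, A, M, D, C, L, h: Hyperparameters
               ) -> ObjectiveBreakdown:
    _check_dims(A, M, D, C, U, X, Y, Z)
    DY = D @ Y
    fit = float(((U - A) ** 2).sum())
    sim = float(((U - M @ X @ DY.T) ** 2).sum())
    attr = float(((U - C @ Z @ DY.T) ** 2).sum()) if C.shape[1] else 0.0
    graph = float(np.trace(U.T @ L @ U))
    sparsity = float(np.abs(U).sum())
    total = (fit + h.alpha1 * sim + h.alpha2 * attr + h.alpha3 * graph
             + h.alpha4 * sparsity)
    return ObjectiveBreakdown(fit, sim, attr, graph, sparsity, total)


# ---------------------------------------------------------------------------
# multiplicative updates: each factor is rescaled entrywise by the ratio of
# the negative to the positive part of its block gradient


def _u_terms(U, X, Y, Z, A, M, D, C, S, W, h):
    DY = D @ Y
    num = 2.0 * A + 2.0 * h.alpha1 * (M @ X @ DY.T) + 2.0 * h.alpha3 * (S @ U)
    den = (2.0 * U + 2.0 * h.alpha1 * U + 2.0 * h.alpha3 * (W @ U)
           + h.alpha4 * np.ones_like(U))
    if C.shape[1]:
        num = num + 2.0 * h.alpha2 * (C @ Z @ DY.T)
        den = den + 2.0 * h.alpha2 * U
    return num, den


def _x_terms(U, X, Y, A, M, D, h):
    DY = D @ Y
    num = M.T @ U @ DY
    den = M.T @ M @ X @ (DY.T @ DY)
    return num, den


def _y_terms(U, X, Y, Z, A, M, D, C, h):
    DY = D @ Y
    MX = M @ X
    num = h.alpha1 * (D.T @ U.T @ MX)
    den = h.alpha1 * (D.T @ DY @ (MX.T @ MX))
    if C.shape[1]:
        CZ = C @ Z
        num = num + h.alpha2 * (D.T @ U.T @ CZ)
        den = den + h.alpha2 * (D.T @ DY @ (CZ.T @ CZ))
    return num, den


def _z_terms(U, Y, Z, D, C, h):
    DY = D @ Y
    num = C.T @ U @ DY
    den = C.T @ C @ Z @ (DY.T @ DY)
    return num, den


def _apply(factor, num, den):
    return factor * (num / (den + DENOM_FLOOR))


def update_U(state: ModelState, data, h: Hyperparameters) -> np.ndarray:
    """One multiplicative update of the score matrix U."""
    A, M, D, C = _arrays(data)
    num, den = _u_terms(state.U, state.X, state.Y, state.Z, A, M, D, C,
                        state.S, state.W, h)
    return _apply(state.U, num, den)


def update_X(state: ModelState, data, h: Hyperparameters) -> np.ndarray:
    """One multiplicative update of the miRNA-similarity projection X."""
    A, M, D, C = _arrays(data)
    num, den = _x_terms(state.U, state.X, state.Y, A, M, D, h)
    return _apply(state.X, num, den)


def update_Y(state: ModelState, data, h: Hyperparameters) -> np.ndarray:
    """One multiplicative update of the disease-similarity projection Y."""
    A, M, D, C = _arrays(data)
    num, den = _y_terms(state.U, state.X, state.Y, state.Z, A, M, D, C, h)
    return _apply(state.Y, num, den)


def update_Z(state: ModelState, data, h: Hyperparameters) -> np.ndarray:
    """One multiplicative update of the node-attribute projection Z."""
    A, M, D, C = _arrays(data)
    if not C.shape[1]:
        return state.Z.copy()
    num, den = _z_terms(state.U, state.Y, state.Z, D, C, h)
    return _apply(state.Z, num, den)


def gradients(state: ModelState, data, h: Hyperparameters
              ) -> dict[str, np.ndarray]:
    """Analytic block gradients of the four sub-objectives.

    For U the l1 term contributes its (constant, all-ones) subgradient,
    valid on the strictly positive orthant where the solver iterates.
    The graph gradient 2*a3*L*U assumes a symmetric neighbour graph.
    """
    A, M, D, C = _arrays(data)
    U, X, Y, Z = state.U, state.X, state.Y, state.Z
    nu, du = _u_terms(U, X, Y, Z, A, M, D, C, state.S, state.W, h)
    nx, dx = _x_terms(U, X, Y, A, M, D, h)
    ny, dy = _y_terms(U, X, Y, Z, A, M, D, C, h)
    out = {
        "U": du - nu,
        "X": 2.0 * h.alpha1 * (dx - nx),
        "Y": 2.0 * (dy - ny),
    }
    if C.shape[1]:
        nz, dz = _z_terms(U, Y, Z, D, C, h)
        out["Z"] = 2.0 * h.alpha2 * (dz - nz)
    else:
        out["Z"] = np.zeros_like(Z)
    return out


def kkt_residuals(state: ModelState, data, h: Hyperparameters
                  ) -> dict[str, float]:
    """Max complementary-slackness residual |factor * gradient| per block."""
    grads = gradients(state, data, h)
    factors = {"U": state.U, "X": state.X, "Y": state.Y, "Z": state.Z}
    return {k: (float(np.abs(factors[k] * g).max()) if g.size else 0.0)
            for k, g in grads.items()}


# ---------------------------------------------------------------------------
# fitting


def _initialize(A, C, h: Hyperparameters, rng: np.random.Generator):
    nm, nd = A.shape
    if h.init_scheme == "warm_start_from_A":
        scale = 0.1 * max(A.mean(), 1e-2)  # floor keeps an all-zero A movable
        U = A + scale * rng.uniform(size=A.shape)
    else:
        U = rng.uniform(size=A.shape)
    X = 0.01 * rng.uniform(size=(nm, h.c))
    Y = 0.01 * rng.uniform(size=(nd, h.c))
    Z = 0.01 * rng.uniform(size=(C.shape[1], h.c))
    return U, X, Y, Z


def fit(data, h: Hyperparameters) -> ModelState:
    """Fit the model by cycling U -> X -> Y -> Z multiplicative updates.

    The objective is recorded once after every full cycle (and once at
    initialization); iteration stops when the change between two adjacent
    cycles falls below ``h.epsilon`` (absolute by default, relative to the
    previous value with ``h.convergence='relative'``) or after
    ``h.max_iter`` cycles.
    """
    A, M, D, C = _arrays(data)
    h.validate_dims(A.shape[0], A.shape[1], C.shape[1])
    rng = np.random.default_rng(h.seed)
    U, X, Y, Z = _initialize(A, C, h, rng)
    graph = build_neighbor_graph(M, h.k_neighbors, h.symmetrize_neighbors)
    lap = graph_laplacian(graph)
    S, W, L = graph.S, lap.W, lap.L
    state = ModelState(U=U, X=X, Y=Y, Z=Z, S=S, W=W, L=L)
    state.objective_trace.append(_objective(U, X, Y, Z, A, M, D, C, L, h))

    for t in range(h.max_iter):
        state.U = _apply(state.U, *_u_terms(state.U, state.X, state.Y,
                                            state.Z, A, M, D, C, S, W, h))
        state.U = _apply_block_check(state.U, "U", t)
        state.X = _apply(state.X, *_x_terms(state.U, state.X, state.Y,
                                            A, M, D, h))
        state.X = _apply_block_check(state.X, "X", t)
        state.Y = _apply(state.Y, *_y_terms(state.U, state.X, state.Y,
                                            state.Z, A, M, D, C, h))
        state.Y = _apply_block_check(state.Y, "Y", t)
        if C.shape[1]:
            state.Z = _apply(state.Z, *_z_terms(state.U, state.Y, state.Z,
                                                D, C, h))
            state.Z = _apply_block_check(state.Z, "Z", t)
        state.n_iter = t + 1
        state.objective_trace.append(
            _objective(state.U, state.X, state.Y, state.Z, A, M, D, C, L, h))
        prev, cur = (state.objective_trace[-2].total,
                     state.objective_trace[-1].total)
        delta = abs(cur - prev)
        if h.convergence == "relative":
            delta = delta / max(abs(prev), 1e-30)
        if delta < h.epsilon:
            state.converged = True
            break
    return state


def _apply_block_check(block: np.ndarray, name: str, iteration: int
                       ) -> np.ndarray:
    if not np.isfinite(block).all():
        raise FloatingPointError(
            f"non-finite values in factor {name} at iteration {iteration}")
    return block


def predict_scores(state: ModelState) -> np.ndarray:
    """Association score matrix U of a fitted model (a copy)."""
    return state.U.copy()


def candidate_ranking(scores: np.ndarray, A_train: np.ndarray,
                      disease: int) -> np.ndarray:
    """miRNA indices for one disease, best score first, excluding pairs
    already positive in the training association matrix."""
    col = scores[:, disease]
    candidates = np.flatnonzero(A_train[:, disease] < 0.5)
    order = np.argsort(-col[candidates], kind="stable")
    return candidates[order]
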