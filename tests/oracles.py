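"""Independent brute-force oracles used by the tests.

Everything here is written with explicit index loops and elementary
operations so that it shares no code path with the package implementation.
"""

import numpy as np


def objective_by_summation(U, X, Y, Z, A, M, D, C, L, h):
    """Objective components by elementwise summation over all indices."""
    nm, nd = A.shape
    c = X.shape[1]
    DY = np.zeros((nd, c))
    for j in range(nd):
        for r in range(c):
            DY[j, r] = sum(D[j, q] * Y[q, r] for q in range(nd))
    MX = np.zeros((nm, c))
    for i in range(nm):
        for r in range(c):
            MX[i, r] = sum(M[i, q] * X[q, r] for q in range(nm))
    CZ = np.zeros((nm, c))
    for i in range(nm):
        for r in range(c):
            CZ[i, r] = sum(C[i, q] * Z[q, r] for q in range(C.shape[1]))
    fit = sim = attr = sparsity = 0.0
    for i in range(nm):
        for j in range(nd):
            fit += (U[i, j] - A[i, j]) ** 2
            sim += (U[i, j] - sum(MX[i, r] * DY[j, r] for r in range(c))) ** 2
            attr += (U[i, j] - sum(CZ[i, r] * DY[j, r] for r in range(c))) ** 2
            sparsity += abs(U[i, j])
    if C.shape[1] == 0:
        attr = 0.0
    graph = 0.0
    for j in range(nd):
        for i in range(nm):
            for k in range(nm):
                graph += U[i, j] * L[i, k] * U[k, j]
    total = (fit + h.alpha1 * sim + h.alpha2 * attr + h.alpha3 * graph
             + h.alpha4 * sparsity)
    return fit, sim, attr, graph, sparsity, total


def _mm(*mats):
    out = mats[0]
    for m in mats[1:]:
        out = np.einsum("ij,jk->ik", out, m)
    return out


def update_U_by_substitution(U, X, Y, Z, A, M, D, C, S, W, h, floor=1e-12):
    """Direct elementwise substitution of the U update rule."""
    DY = _mm(D, Y)
    num = 2 * A + 2 * h.alpha1 * _mm(M, X, DY.T) + 2 * h.alpha3 * _mm(S, U)
    den = (2 * U + 2 * h.alpha1 * U + 2 * h.alpha3 * _mm(W, U)
           + h.alpha4 * np.ones_like(U))
    if C.shape[1]:
        num = num + 2 * h.alpha2 * _mm(C, Z, DY.T)
        den = den + 2 * h.alpha2 * U
    new = np.empty_like(U)
    for i in range(U.shape[0]):
        for j in range(U.shape[1]):
            new[i, j] = U[i, j] * num[i, j] / (den[i, j] + floor)
    return new


def update_X_by_substitution(U, X, Y, A, M, D, h, floor=1e-12):
    DY = _mm(D, Y)
    num = _mm(M.T, U, DY)
    den = _mm(M.T, M, X, DY.T, DY)
    return X * num / (den + floor)


def update_Y_by_substitution(U, X, Y, Z, A, M, D, C, h, floor=1e-12):
    DY = _mm(D, Y)
    MX = _mm(M, X)
    num = h.alpha1 * _mm(D.T, U.T, MX)
    den = h.alpha1 * _mm(D.T, DY, MX.T, MX)
    if C.shape[1]:
        CZ = _mm(C, Z)
        num = num + h.alpha2 * _mm(D.T, U.T, CZ)
        den = den + h.alpha2 * _mm(D.T, DY, CZ.T, CZ)
    return Y * num / (den + floor)


def update_Z_by_substitution(U, Y, Z, D, C, h, floor=1e-12):
    DY = _mm(D, Y)
    num = _mm(C.T, U, DY)
    den = _mm(C.T, C, Z, DY.T, DY)
    return Z * num / (den + floor)


def auc_by_pair_counting(pos, neg):
    """Fraction of (pos, neg) pairs with pos > neg; ties count one half."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def aupr_by_threshold_enumeration(pos, neg):
    """PR area by enumerating every distinct score as a threshold and
    applying the trapezoid on the recall-sorted curve with a left anchor."""
    pos = list(pos)
    neg = list(neg)
    points = []
    # descending thresholds make recall non-decreasing, so the point list
    # is already recall-sorted with ties kept in sweep order
    for t in sorted(set(pos + neg), reverse=True):
        tp = sum(1 for s in pos if s >= t)
        fp = sum(1 for s in neg if s >= t)
        points.append((tp / len(pos), tp / (tp + fp)))
    recalls = [0.0] + [r for r, _ in points]
    precisions = [points[0][1]] + [p for _, p in points]
    area = 0.0
    for a, b in zip(range(len(recalls) - 1), range(1, len(recalls))):
        area += (recalls[b] - recalls[a]) * (precisions[a] + precisions[b]) / 2
    return area


def laplacian_quadratic_by_double_sum(S, U):
    """(1/2) sum_ij S_ij ||U_i - U_j||^2 by brute-force double summation."""
    total = 0.0
    for i in range(S.shape[0]):
        for j in range(S.shape[0]):
            total += S[i, j] * ((U[i] - U[j]) ** 2).sum()
    return 0.5 * total
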