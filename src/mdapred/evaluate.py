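"""Five-fold cross-validation over known associations and ranking metrics.

Known positive (miRNA, disease) cells are partitioned into five near-equal
folds; each fold in turn is masked to zero in the training matrix, the
model is refit, and the held-out positives of each evaluated disease are
ranked against that disease's never-associated miRNAs.  Per-disease AUC,
AUPR and top-k recall are averaged over folds and then over diseases.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .io import AssociationMatrix, Dataset, Hyperparameters
from .similarity import mirna_functional_similarity
from . import model as _model

log = logging.getLogger("mdapred")

__all__ = [
    "FoldPlan",
    "EvaluationReport",
    "make_folds",
    "mask_fold",
    "rank_auc",
    "pr_aupr",
    "top_k_recall",
    "select_evaluated_diseases",
    "most_annotated_diseases",
    "run_cross_validation",
    "paired_auc_test",
]

CURVE_GRID = 1000  # fixed FPR/recall grid for vertical curve averaging


@dataclass
class FoldPlan:
    """Disjoint partition of the positive cells into near-equal folds."""

    folds: list[np.ndarray]  # each an (n_f, 2) array of (miRNA, disease) indices
    seed: int


@dataclass
class DiseaseMetrics:
    auc: float
    aupr: float
    topk_recall: dict[int, float]
    roc_curve: tuple[np.ndarray, np.ndarray]  # (fpr grid, mean tpr)
    pr_curve: tuple[np.ndarray, np.ndarray]   # (recall grid, mean precision)
    n_folds_used: int


@dataclass
class EvaluationReport:
    per_disease: dict[str, DiseaseMetrics]
    averages: dict[str, float]
    topk_average: dict[int, float] = field(default_factory=dict)
    pvalues: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "averages": self.averages,
            "topk_average": {int(k): v for k, v in self.topk_average.items()},
            "per_disease": {
                d: {"auc": m.auc, "aupr": m.aupr,
                    "topk_recall": {int(k): v for k, v in m.topk_recall.items()},
                    "n_folds_used": m.n_folds_used}
                for d, m in self.per_disease.items()
            },
            "pvalues": self.pvalues,
        }


def make_folds(A: AssociationMatrix | np.ndarray, seed: int,
               n_folds: int = 5) -> FoldPlan:
    """Seeded uniform random partition of positive cells into near-equal folds."""
    values = A.values if isinstance(A, AssociationMatrix) else np.asarray(A)
    pos = np.argwhere(values > 0.5)
    if len(pos) < n_folds:
        raise ValueError(
            f"need at least {n_folds} positive associations, found {len(pos)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pos))
    folds = [pos[idx] for idx in np.array_split(perm, n_folds)]
    return FoldPlan(folds=folds, seed=seed)


def mask_fold(A: AssociationMatrix | np.ndarray,
              fold: np.ndarray) -> np.ndarray:
    """Training matrix with the fold's positive cells set to 0 (copy)."""
    values = A.values if isinstance(A, AssociationMatrix) else np.asarray(A)
    out = values.copy()
    fold = np.asarray(fold).reshape(-1, 2)
    if len(fold) and not (values[fold[:, 0], fold[:, 1]] > 0.5).all():
        bad = fold[~(values[fold[:, 0], fold[:, 1]] > 0.5)][0]
        raise ValueError(f"fold cell {tuple(bad)} is not a positive of A")
    out[fold[:, 0], fold[:, 1]] = 0.0
    return out


def rank_auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Probability that a random positive outscores a random negative.

    Computed from the rank-sum statistic; ties count one half.  Equivalent
    to the area under the threshold-sweep ROC curve.
    """
    pos = np.asarray(pos_scores, float)
    neg = np.asarray(neg_scores, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("rank_auc needs nonempty positive and negative lists")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    rank_sum = ranks[: pos.size].sum()
    return float((rank_sum - pos.size * (pos.size + 1) / 2.0)
                 / (pos.size * neg.size))


def _pr_points(pos: np.ndarray, neg: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Precision and recall at every distinct score threshold, descending."""
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    thresholds = np.unique(scores)[::-1]
    tp = np.array([(labels[scores >= t] == 1).sum() for t in thresholds],
                  float)
    pred = np.array([(scores >= t).sum() for t in thresholds], float)
    precision = tp / pred
    recall = tp / pos.size
    return recall, precision


def pr_aupr(pos_scores: Sequence[float], neg_scores: Sequence[float]
            ) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """Precision-recall curve and its trapezoidal area.

    The stepwise curve over distinct-score thresholds is sorted by recall;
    a (0, precision-at-first-threshold) anchor closes the left end.
    """
    pos = np.asarray(pos_scores, float)
    neg = np.asarray(neg_scores, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("pr_aupr needs nonempty positive and negative lists")
    recall, precision = _pr_points(pos, neg)
    r = np.concatenate([[0.0], recall])
    p = np.concatenate([[precision[0]], precision])
    aupr = float(np.trapezoid(p, r))
    return (recall, precision), aupr


def average_precision(pos_scores, neg_scores) -> float:
    """Average-precision estimator of the PR area (sum of precision x
    recall increments), offered as an alternative to the trapezoid."""
    pos = np.asarray(pos_scores, float)
    neg = np.asarray(neg_scores, float)
    recall, precision = _pr_points(pos, neg)
    r = np.concatenate([[0.0], recall])
    return float(np.sum(np.diff(r) * precision))


def top_k_recall(ranked_labels: Sequence[int], k: int, total_pos: int) -> float:
    """Fraction of all positives appearing among the first k ranked items."""
    if total_pos < 1:
        raise ValueError("total_pos must be >= 1")
    labels = np.asarray(ranked_labels)
    if k < 1 or k > labels.size:
        raise ValueError(f"k={k} must be in [1, {labels.size}]")
    return float(labels[:k].sum() / total_pos)


def select_evaluated_diseases(A: AssociationMatrix,
                              min_positives: int = 80) -> list[str]:
    """Diseases with at least ``min_positives`` known associated miRNAs."""
    counts = A.values.sum(axis=0)
    return [d for d, n in zip(A.disease_ids, counts) if n >= min_positives]


def most_annotated_diseases(A: AssociationMatrix, n: int = 15) -> list[str]:
    """The ``n`` diseases with the most known associations (ties by column
    order).  The evaluation protocol scores only well-characterized
    diseases; this picks the synthetic analogue of that common-disease set."""
    counts = A.values.sum(axis=0)
    order = np.argsort(-counts, kind="stable")[:n]
    return [A.disease_ids[j] for j in order]


def _fold_scores(data: Dataset, h: Hyperparameters, A_train: np.ndarray,
                 similarity_source: str,
                 scorer: Callable | None) -> np.ndarray:
    if scorer is not None:
        return np.asarray(scorer(A_train, data, h), float)
    M = data.M
    if similarity_source == "functional":
        # leakage-free: recompute miRNA similarity from the training fold only
        A_obj = AssociationMatrix(A_train, data.A.mirna_ids, data.A.disease_ids)
        M = mirna_functional_similarity(A_obj, data.D)
    elif similarity_source != "given":
        raise ValueError(f"unknown similarity_source {similarity_source!r}")
    state = _model.fit((A_train, M.values, data.D.values, data.C.values), h)
    return state.U


def run_cross_validation(data: Dataset, h: Hyperparameters,
                         evaluated_diseases: Sequence[str] | None = None,
                         seed: int = 0, n_folds: int = 5,
                         similarity_source: str = "given",
                         scorer: Callable | None = None,
                         ks: Sequence[int] = (30, 60, 90),
                         pooled: bool = False) -> EvaluationReport:
    """Run the full masked cross-validation protocol.

    For each fold the fold's positives are removed from the training
    matrix, a score matrix is produced (by fitting the model, or by
    ``scorer(A_train, data, h)`` when injected), and each evaluated
    disease's held-out positives are ranked against its never-associated
    miRNAs; training positives are excluded from the candidate pool.
    ``pooled=True`` additionally pools all evaluated diseases' scores per
    fold into a single ranking (reported under averages as pooled_auc).
    """
    A_full = data.A.values
    ids = data.A.disease_ids
    if evaluated_diseases is None:
        evaluated_diseases = list(ids)
    unknown = [d for d in evaluated_diseases if d not in ids]
    if unknown:
        raise ValueError(f"evaluated diseases not in dataset: {unknown}")
    plan = make_folds(data.A, seed=seed, n_folds=n_folds)
    fold_U: list[np.ndarray] = []
    fold_train: list[np.ndarray] = []
    for fold in plan.folds:
        A_train = mask_fold(data.A, fold)
        fold_U.append(_fold_scores(data, h, A_train, similarity_source, scorer))
        fold_train.append(A_train)

    fpr_grid = np.linspace(0, 1, CURVE_GRID)
    rec_grid = np.linspace(0, 1, CURVE_GRID)
    per_disease: dict[str, DiseaseMetrics] = {}
    pooled_pos: list[np.ndarray] = []
    pooled_neg: list[np.ndarray] = []
    for d in evaluated_diseases:
        j = ids.index(d)
        aucs, auprs, tprs, precs = [], [], [], []
        topk: dict[int, list[float]] = {k: [] for k in ks}
        for fold, A_train, U in zip(plan.folds, fold_train, fold_U):
            test_rows = fold[fold[:, 1] == j, 0]
            if test_rows.size == 0:
                continue
            neg_rows = np.flatnonzero(A_full[:, j] < 0.5)
            pos = U[test_rows, j]
            neg = U[neg_rows, j]
            aucs.append(rank_auc(pos, neg))
            (recall, precision), aupr = pr_aupr(pos, neg)
            auprs.append(aupr)
            tprs.append(_roc_on_grid(pos, neg, fpr_grid))
            order = np.argsort(recall)
            precs.append(np.interp(rec_grid, recall[order], precision[order]))
            labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
            scores = np.concatenate([pos, neg])
            ranked = labels[np.argsort(-scores, kind="stable")]
            for k in ks:
                kk = min(k, ranked.size)
                topk[k].append(top_k_recall(ranked, kk, int(pos.size)))
            if pooled:
                pooled_pos.append(pos)
                pooled_neg.append(neg)
        if not aucs:
            warnings.warn(f"disease {d!r} has no held-out positives in any "
                          f"fold; excluded from the report")
            continue
        per_disease[d] = DiseaseMetrics(
            auc=float(np.mean(aucs)),
            aupr=float(np.mean(auprs)),
            topk_recall={k: float(np.mean(v)) for k, v in topk.items()},
            roc_curve=(fpr_grid, np.mean(tprs, axis=0)),
            pr_curve=(rec_grid, np.mean(precs, axis=0)),
            n_folds_used=len(aucs),
        )
    if not per_disease:
        raise ValueError("no evaluated disease had held-out positives")
    averages = {
        "auc": float(np.mean([m.auc for m in per_disease.values()])),
        "aupr": float(np.mean([m.aupr for m in per_disease.values()])),
    }
    if pooled and pooled_pos:
        averages["pooled_auc"] = rank_auc(np.concatenate(pooled_pos),
                                          np.concatenate(pooled_neg))
    topk_average = {
        k: float(np.mean([m.topk_recall[k] for m in per_disease.values()]))
        for k in ks
    }
    return EvaluationReport(per_disease=per_disease, averages=averages,
                            topk_average=topk_average)


def _roc_on_grid(pos: np.ndarray, neg: np.ndarray,
                 fpr_grid: np.ndarray) -> np.ndarray:
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    order = np.argsort(-scores, kind="stable")
    tp = np.concatenate([[0], np.cumsum(labels[order])])
    fp = np.concatenate([[0], np.cumsum(1 - labels[order])])
    return np.interp(fpr_grid, fp / neg.size, tp / pos.size)


def paired_auc_test(auc_a: Sequence[float], auc_b: Sequence[float]
                    ) -> tuple[float, float]:
    """Two-sided paired t-test on per-disease metric differences.

    Returns (t statistic, p-value) with n-1 degrees of freedom.  A
    zero-variance difference vector yields p = 1.0 when the mean
    difference is 0, else the degenerate limit p = 0.0 with a warning.
    """
    a = np.asarray(auc_a, float)
    b = np.asarray(auc_b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired test needs equal-length lists of length >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd < 1e-12:  # constant differences up to float rounding
        if abs(diff.mean()) < 1e-12:
            return 0.0, 1.0
        warnings.warn("zero-variance nonzero differences: p reported as the "
                      "degenerate limit 0.0")
        return math.copysign(math.inf, diff.mean()), 0.0
    t = diff.mean() / (sd / math.sqrt(diff.size))
    p = 2.0 * stats.t.sf(abs(t), df=diff.size - 1)
    return float(t), float(p)
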