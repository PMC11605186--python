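"""ROC analysis, cross-condition transfer testing, and condition clustering.

AUROC is computed two independent ways that must agree: the rank-based
pairwise-concordance statistic (probability that a random positive
outscores a random negative, ties half-credited — the Mann–Whitney
convention) and the trapezoidal area under the ROC curve built by
sweeping thresholds over the unique scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .exceptions import EvaluationError, ParameterError


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float


def _check_labels(scores, labels):
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    if scores.shape != labels.shape:
        raise ParameterError("scores and labels must align")
    if not ((labels == 0) | (labels == 1)).all():
        raise ParameterError("labels must be 0/1")
    if labels.min() == labels.max():
        raise EvaluationError("both classes required to evaluate a ROC curve")
    return scores, labels


def roc_curve(scores, labels) -> ROCResult:
    """ROC by threshold sweep over unique scores; tied scores form one step.

    TPR = TP/(TP+FN), FPR = FP/(FP+TN) at each threshold (predict positive
    when score >= threshold); the curve runs from (0,0) to (1,1) and the
    reported AUROC is its trapezoidal area.
    """
    scores, labels = _check_labels(scores, labels)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    distinct = np.flatnonzero(np.r_[np.diff(s) != 0, True])
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    tpr = np.r_[0.0, tp / n1]
    fpr = np.r_[0.0, fp / n0]
    thresholds = np.r_[np.inf, s[distinct]]
    area = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds, fpr, tpr, area)


def auroc(scores, labels) -> float:
    """Pairwise-concordance AUROC: (concordant + 0.5 * tied) / (n1 * n0)."""
    scores, labels = _check_labels(scores, labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = rankdata(scores)  # average ranks handle ties as half-credit
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class CrossTestMatrix:
    """K x K transfer matrix: row model evaluated on column test split."""

    condition_ids: list[str]
    matrix: np.ndarray
    linkage: Optional[np.ndarray] = None

    def __post_init__(self):
        k = len(self.condition_ids)
        if self.matrix.shape != (k, k):
            raise ParameterError("matrix must be K x K")

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.matrix)


def cross_test(models: dict, datasets: dict) -> CrossTestMatrix:
    """Evaluate every model on every condition-pair's held-out test split.

    ``models`` maps condition id -> fitted classifier with predict_proba;
    ``datasets`` maps condition id -> (X_test, y_test).  Feature widths
    must agree across all models and datasets.
    """
    ids = list(models.keys())
    if set(ids) != set(datasets.keys()):
        raise ParameterError("models and datasets must cover the same conditions")
    k = len(ids)
    M = np.empty((k, k))
    for i, mid in enumerate(ids):
        model = models[mid]
        for j, did in enumerate(ids):
            X, y = datasets[did]
            width = X.shape[1] if X.ndim == 2 else int(np.prod(X.shape[1:]))
            expect = getattr(model, "n_features_in_", width)
            if expect != width:
                raise ParameterError(
                    f"model {mid!r} expects {expect} features, dataset "
                    f"{did!r} provides {width}"
                )
            M[i, j] = auroc(model.predict_proba(X)[:, 1], y)
    return CrossTestMatrix(ids, M)


def cluster_conditions(ct: CrossTestMatrix, n_clusters: int = 2):
    """Average-linkage clustering of conditions on symmetrized 1-AUROC.

    Distance d(i,j) = 1 - (M[i,j] + M[j,i]) / 2, clipped to [0,1].
    Returns (linkage matrix, flat cluster labels at ``n_clusters``).
    """
    k = len(ct.condition_ids)
    if k < 2:
        raise ParameterError("need at least two conditions to cluster")
    D = 1.0 - (ct.matrix + ct.matrix.T) / 2.0
    D = np.clip(D, 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    ct.linkage = Z
    return Z, labels
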