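"""ROC evaluation: sensitivity, specificity, accuracy, AUC with SE.

AUC is the Mann-Whitney pairwise-concordance statistic (ties count one
half); its standard error uses the Hanley-McNeil formula.  Operating
points default to the Youden-optimal threshold.  Both apparent
(resubstitution) and stratified cross-validated metrics are offered,
since screening performance claims should rest on held-out scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .classify import NeovascularizationClassifier

__all__ = [
    "mann_whitney_auc",
    "hanley_mcneil_se",
    "ROCResult",
    "roc_metrics",
    "score",
    "cross_validated_scores",
]


def mann_whitney_auc(scores, labels) -> float:
    """P(score_pos > score_neg) + 0.5 P(tie), via average ranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0)
                 / (n0 * n1))


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil (1982) standard error of a trapezoidal AUC."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2)
           + (n_neg - 1) * (q2 - auc**2)) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


@dataclass
class ROCResult:
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    auc_se: float
    threshold: float
    curve: list = field(default_factory=list)  # (FPR, TPR) points

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "auc_se": self.auc_se,
            "threshold": self.threshold,
        }


def roc_metrics(scores, labels, threshold: float | None = None
                ) -> ROCResult:
    """Full ROC summary at a threshold (default: Youden-optimal)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    auc = mann_whitney_auc(scores, labels)
    se = hanley_mcneil_se(auc, n1, n0)
    fpr, tpr, thr = roc_curve(labels, scores)
    if threshold is None:
        threshold = float(thr[np.argmax(tpr - fpr)])
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    return ROCResult(
        sensitivity=tp / n1,
        specificity=tn / n0,
        accuracy=(tp + tn) / labels.size,
        auc=auc, auc_se=se, threshold=float(threshold),
        curve=list(zip(fpr.tolist(), tpr.tolist())),
    )


def score(X, ensemble) -> np.ndarray:
    """Model-averaged predicted probabilities for rows of ``X`` (on the
    representation the ensemble's models were fitted on)."""
    return ensemble.predict_proba(np.asarray(X, dtype=float))


def cross_validated_scores(X, y, classifier=None, n_splits: int = 5,
                           random_state: int = 0) -> np.ndarray:
    """Held-out probabilities from stratified k-fold refits of the full
    reduction + selection chain (no information leaks across folds)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if classifier is None:
        classifier = NeovascularizationClassifier()
    out = np.empty(y.size)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                          random_state=random_state)
    for train, test in skf.split(X, y):
        from sklearn.base import clone
        clf = clone(classifier).fit(X[train], y[train])
        out[test] = clf.predict_proba(X[test])[:, 1]
    return out
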