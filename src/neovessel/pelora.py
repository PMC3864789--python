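"""Supervised penalized-logistic feature clustering (Pelora-style).

Reduces the 75-column feature table to a handful of cluster
representatives.  Clusters are grown greedily: starting from the single
(possibly sign-flipped) standardized feature that minimizes a ridge-
penalized logistic deviance of the class labels on the current
representatives, features are added to the cluster whenever replacing
the representative by the mean of the enlarged, sign-adjusted member
set improves the criterion.  Selection, clustering and classification
signal thus come from one supervised objective, which behaves well
under the strong class imbalance typical of screening cohorts.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

__all__ = ["ridge_logistic", "PeloraReducer"]


def ridge_logistic(X: np.ndarray, y: np.ndarray, lam: float,
                   max_iter: int = 25, tol: float = 1e-9):
    """Ridge-penalized logistic regression via IRLS.

    ``X`` must already contain an intercept column (first column, which
    is not penalized).  Returns (beta, deviance, penalized_deviance).
    """
    n, k = X.shape
    beta = np.zeros(k)
    pen = np.full(k, 2.0 * lam)
    pen[0] = 0.0
    prev = np.inf
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = np.maximum(p * (1 - p), 1e-10)
        z = eta + (y - p) / w
        xtw = X.T * w
        beta = np.linalg.solve(xtw @ X + np.diag(pen), xtw @ z)
        obj = _penalized_deviance(X, y, beta, lam)
        if abs(prev - obj) < tol * (1 + abs(obj)):
            break
        prev = obj
    dev = _deviance(X, y, beta)
    return beta, dev, dev + 2.0 * lam * float(beta[1:] @ beta[1:])


def _deviance(X, y, beta) -> float:
    eta = np.clip(X @ beta, -30, 30)
    ll = y * eta - np.log1p(np.exp(eta))
    return float(-2.0 * ll.sum())


def _penalized_deviance(X, y, beta, lam) -> float:
    return _deviance(X, y, beta) + 2.0 * lam * float(beta[1:] @ beta[1:])


class PeloraReducer(BaseEstimator, TransformerMixin):
    """Greedy supervised feature clustering with a penalized logistic
    criterion.

    Parameters
    ----------
    n_clusters : int
        Maximum number of clusters K (each yields one representative).
    lam : float or None
        Ridge penalty weight; ``None`` uses 0.01 * n_samples at fit
        time.
    min_improvement : float or None
        A candidate joins a growing cluster only if it lowers the
        penalized deviance by more than this amount, or leaves it
        exactly unchanged (the exact-duplicate tie case).  ``None``
        (default) uses the multiplicity-calibrated bound
        2 ln(number of candidate additions), the chi-square(1) Bonferroni
        level that keeps chance admissions rare under a pure-noise
        table.

    Attributes
    ----------
    clusters_ : list of int arrays — feature indices per cluster
    signs_ : list of int arrays — per-feature sign (+1 / -1)
    means_, scales_ : standardization parameters of the input columns
    n_clusters_ : number of clusters actually built
    """

    def __init__(self, n_clusters: int = 5, lam: float | None = None,
                 min_improvement: float | None = None):
        self.n_clusters = n_clusters
        self.lam = lam
        self.min_improvement = min_improvement

    def _criterion(self, reps: list[np.ndarray], trial: np.ndarray,
                   y: np.ndarray, lam: float) -> float:
        cols = [np.ones_like(y, dtype=float)] + reps + [trial]
        _, _, pen = ridge_logistic(np.column_stack(cols), y, lam,
                                   max_iter=12)
        return pen

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        y = np.asarray(y, dtype=float)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("labels must contain both classes")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        n, p = X.shape
        lam = 0.01 * n if self.lam is None else float(self.lam)

        self.means_ = X.mean(axis=0)
        self.scales_ = X.std(axis=0)
        self.scales_[self.scales_ < 1e-12] = 1.0
        Z = (X - self.means_) / self.scales_

        remaining = list(range(p))
        clusters: list[np.ndarray] = []
        signs: list[np.ndarray] = []
        reps: list[np.ndarray] = []

        for _ in range(self.n_clusters):
            if not remaining:
                break
            # seed: best single sign-adjusted feature
            best = None
            for j in remaining:
                for s in (1.0, -1.0):
                    crit = self._criterion(reps, s * Z[:, j], y, lam)
                    if best is None or crit < best[0]:
                        best = (crit, j, s)
            crit0, j0, s0 = best
            members, msigns = [j0], [s0]
            remaining.remove(j0)
            current = crit0
            # grow while the criterion improves (ties admit duplicates)
            while remaining:
                cand = None
                tie = None
                base = np.sum([s * Z[:, j] for j, s in
                               zip(members, msigns)], axis=0)
                m = len(members)
                for j in remaining:
                    for s in (1.0, -1.0):
                        rep = (base + s * Z[:, j]) / (m + 1)
                        crit = self._criterion(reps, rep, y, lam)
                        if cand is None or crit < cand[0]:
                            cand = (crit, j, s)
                        if tie is None and abs(crit - current) < 1e-10:
                            tie = (crit, j, s)
                crit1, j1, s1 = cand
                if self.min_improvement is None:
                    thresh = 2.0 * np.log(max(2 * len(remaining), 2))
                else:
                    thresh = self.min_improvement
                if current - crit1 <= thresh:
                    # exact ties (duplicated measurements) still join
                    if tie is None:
                        break
                    crit1, j1, s1 = tie
                members.append(j1)
                msigns.append(s1)
                remaining.remove(j1)
                current = crit1
            clusters.append(np.asarray(members, dtype=int))
            signs.append(np.asarray(msigns))
            rep = np.mean([s * Z[:, j] for j, s in
                           zip(members, msigns)], axis=0)
            reps.append(rep)

        self.clusters_ = clusters
        self.signs_ = signs
        self.n_clusters_ = len(clusters)
        self.n_features_in_ = p
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "clusters_")
        X = np.asarray(X, dtype=float)
        Z = (X - self.means_) / self.scales_
        reps = [np.mean(s * Z[:, c], axis=1)
                for c, s in zip(self.clusters_, self.signs_)]
        return np.column_stack(reps)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "clusters_")
        return np.asarray([f"cluster{k}" for k in
                           range(self.n_clusters_)], dtype=object)
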