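"""End-to-end classifier over a per-image feature table.

``NeovascularizationClassifier`` chains the Pelora reduction, the AICc
model search with optional pairwise interactions, and (optionally)
bootstrap-smoothed model averaging into one scikit-learn classifier
usable with sklearn model selection and pipelines.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .modelsearch import (akaike_weights, build_ensemble,
                          enumerate_and_rank, multimodel_infer)
from .pelora import PeloraReducer

__all__ = ["NeovascularizationClassifier"]


class NeovascularizationClassifier(BaseEstimator, ClassifierMixin):
    """Pelora reduction + AICc-ranked logistic models + model averaging.

    Parameters
    ----------
    n_clusters : int
        Number of Pelora clusters (candidate main effects).
    lam : float or None
        Pelora ridge penalty (None = 0.01 * n at fit time).
    with_interactions : bool
        Allow pairwise interaction terms between representatives.
    bootstrap : int
        Number of bootstrap replicates for weight smoothing; 0 uses
        plain full-data Akaike weights.
    top_models : int
        Number of top-AICc models entering the averaging stage.
    random_state : int
        Seed for the bootstrap resampling.
    """

    def __init__(self, n_clusters: int = 5, lam: float | None = None,
                 with_interactions: bool = True, bootstrap: int = 0,
                 top_models: int = 20, random_state: int = 0):
        self.n_clusters = n_clusters
        self.lam = lam
        self.with_interactions = with_interactions
        self.bootstrap = bootstrap
        self.top_models = top_models
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("binary labels required")
        yb = (y == self.classes_[1]).astype(float)

        self.reducer_ = PeloraReducer(n_clusters=self.n_clusters,
                                      lam=self.lam).fit(X, yb)
        R = self.reducer_.transform(X)
        names = list(self.reducer_.get_feature_names_out())
        self.models_ = enumerate_and_rank(
            R, yb, with_interactions=self.with_interactions, names=names,
            random_state=self.random_state)
        top = self.models_[: self.top_models]
        if self.bootstrap > 0:
            self.ensemble_ = multimodel_infer(
                R, yb, top, B=self.bootstrap, seed=self.random_state,
                names=names)
        else:
            w = akaike_weights(np.array([m.aicc for m in top]))
            self.ensemble_ = build_ensemble(top, w)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "ensemble_")
        R = self.reducer_.transform(np.asarray(X, dtype=float))
        p1 = self.ensemble_.predict_proba(R)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p >= 0.5).astype(int)]

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]
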