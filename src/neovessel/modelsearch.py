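"""Exhaustive GLM search with pairwise interactions, AICc ranking and
bootstrap-smoothed multimodel inference.

Given a small set of predictors (typically the cluster representatives
from the Pelora reduction), every admissible logistic model built from
main effects and, optionally, their pairwise interactions is fitted,
with marginality enforced (an interaction term requires both of its
main effects).  Models are ranked by the small-sample-corrected Akaike
criterion

    AIC  = 2 k - 2 loglik
    AICc = AIC + 2 k (k + 1) / (n - k - 1).

Model-selection uncertainty is handled by stratified bootstrap
resampling: each replicate re-ranks the candidate models, per-replicate
Akaike weights exp(-delta/2)/sum(...) are averaged into smoothed
weights, and coefficients are model-averaged with a variance split into
a within-model (sampling) part and a between-model (selection) part.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .pelora import ridge_logistic

logger = logging.getLogger(__name__)

__all__ = [
    "aicc_score",
    "CandidateModel",
    "ModelEnsemble",
    "admissible_term_sets",
    "enumerate_and_rank",
    "akaike_weights",
    "multimodel_infer",
    "build_ensemble",
]

_COEF_CAP = 15.0  # |coef| beyond this on standardized inputs => separation


def aicc_score(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; +inf when n <= k + 1."""
    if n <= k + 1:
        return float("inf")
    aic = 2.0 * k - 2.0 * loglik
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class CandidateModel:
    """One fitted logistic model over a term subset."""

    mains: tuple[int, ...]
    interactions: tuple[tuple[int, int], ...]
    terms: tuple[str, ...] = ()
    coef: np.ndarray = field(default_factory=lambda: np.zeros(0))
    se: np.ndarray = field(default_factory=lambda: np.zeros(0))
    loglik: float = 0.0
    k: int = 0
    aic: float = float("inf")
    aicc: float = float("inf")
    ridge_fallback: bool = False

    def design(self, X: np.ndarray) -> np.ndarray:
        cols = [np.ones(X.shape[0])]
        for j in self.mains:
            cols.append(X[:, j])
        for a, b in self.interactions:
            cols.append(X[:, a] * X[:, b])
        return np.column_stack(cols)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = np.clip(self.design(X) @ self.coef, -30, 30)
        return 1.0 / (1.0 + np.exp(-eta))


def _term_names(mains, interactions, names) -> tuple[str, ...]:
    out = ["(intercept)"]
    out += [names[j] for j in mains]
    out += [f"{names[a]}:{names[b]}" for a, b in interactions]
    return tuple(out)


def admissible_term_sets(n_mains: int, with_interactions: bool):
    """All (mains, interactions) subsets under marginality."""
    out = []
    for r in range(n_mains + 1):
        for mains in itertools.combinations(range(n_mains), r):
            pairs = list(itertools.combinations(mains, 2))
            if with_interactions and pairs:
                for ir in range(len(pairs) + 1):
                    for inter in itertools.combinations(pairs, ir):
                        out.append((mains, inter))
            else:
                out.append((mains, ()))
    return out


def _fit_model(X: np.ndarray, y: np.ndarray, mains, interactions,
               names) -> CandidateModel:
    model = CandidateModel(mains=tuple(mains),
                           interactions=tuple(interactions),
                           terms=_term_names(mains, interactions, names))
    design = model.design(X)
    n, k = design.shape
    fallback = False
    coef = se = None
    loglik = -np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(
                maxiter=50)
            coef = np.asarray(res.params)
            se = np.asarray(res.bse)
            loglik = float(res.llf)
            if (not np.isfinite(coef).all()
                    or np.abs(coef).max() > _COEF_CAP
                    or not np.isfinite(se).all()):
                fallback = True
        except Exception:
            fallback = True
    if fallback:
        # quasi-separation: stabilize with a light ridge; report the
        # unpenalized likelihood of the capped fit
        lam = 1e-2 * n
        beta, dev, _ = ridge_logistic(design, y.astype(float), lam)
        coef = beta
        p = 1.0 / (1.0 + np.exp(-np.clip(design @ beta, -30, 30)))
        w = np.maximum(p * (1 - p), 1e-10)
        cov = np.linalg.pinv((design.T * w) @ design
                             + np.diag(np.r_[0.0, np.full(k - 1, 2 * lam)]))
        se = np.sqrt(np.diag(cov))
        loglik = -dev / 2.0
    model.coef = coef
    model.se = se
    model.loglik = loglik
    model.k = k
    model.aic = 2.0 * k - 2.0 * loglik
    model.aicc = aicc_score(loglik, k, n)
    model.ridge_fallback = fallback
    return model


def enumerate_and_rank(X: np.ndarray, y: np.ndarray,
                       with_interactions: bool = True,
                       names: list[str] | None = None,
                       max_exhaustive_terms: int = 20,
                       random_state: int = 0) -> list[CandidateModel]:
    """Fit every admissible term subset and rank by AICc (ascending).

    Falls back to a seeded genetic search over term-inclusion bitmasks
    when the candidate term count exceeds ``max_exhaustive_terms``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m = X.shape[1]
    if names is None:
        names = [f"x{j}" for j in range(m)]
    n_terms = m + (m * (m - 1) // 2 if with_interactions else 0)
    if n_terms <= max_exhaustive_terms:
        subsets = admissible_term_sets(m, with_interactions)
    else:
        subsets = _genetic_search(X, y, with_interactions, names,
                                  random_state)
    models = [_fit_model(X, y, mains, inter, names)
              for mains, inter in subsets]
    models.sort(key=lambda md: md.aicc)
    return models


def _repair(mask_m, mask_i, pairs):
    """Enforce marginality: drop interactions missing a main effect."""
    return [mi and mask_m[a] and mask_m[b]
            for mi, (a, b) in zip(mask_i, pairs)]


def _genetic_search(X, y, with_interactions, names, random_state,
                    population: int = 100, generations: int = 200,
                    keep: int = 64):
    """Seeded GA over admissible term subsets; returns distinct subsets
    of the final hall of fame."""
    rng = np.random.default_rng(random_state)
    m = X.shape[1]
    pairs = (list(itertools.combinations(range(m), 2))
             if with_interactions else [])

    def fitness(mm, mi):
        mains = tuple(j for j in range(m) if mm[j])
        inter = tuple(p for p, on in zip(pairs, mi) if on)
        return _fit_model(X, y, mains, inter, names).aicc

    pop = [(list(rng.random(m) < 0.5),
            _repair(list(rng.random(len(pairs)) < 0.25),
                    list(rng.random(len(pairs)) < 0.25), pairs)
            if pairs else [])
           for _ in range(population)]
    pop = [(mm, _repair([True] * len(pairs), mi, pairs) if pairs else [])
           for mm, mi in [(mm, mi) for mm, mi in pop]]
    scores = {}

    def key(ind):
        return (tuple(ind[0]), tuple(ind[1]))

    for gen in range(generations):
        for ind in pop:
            k = key(ind)
            if k not in scores:
                scores[k] = fitness(*ind)
        ranked = sorted(pop, key=lambda ind: scores[key(ind)])
        elite = ranked[: population // 4]
        children = list(elite)
        while len(children) < population:
            pa, pb = rng.choice(len(elite), 2)
            cm = [elite[pa][0][j] if rng.random() < 0.5 else elite[pb][0][j]
                  for j in range(m)]
            ci = [elite[pa][1][j] if rng.random() < 0.5 else elite[pb][1][j]
                  for j in range(len(pairs))]
            # mutation
            cm = [v ^ (rng.random() < 0.05) for v in cm]
            ci = [v ^ (rng.random() < 0.05) for v in ci]
            children.append((cm, _repair(cm, ci, pairs) if pairs else []))
        pop = children
    best = sorted(scores.items(), key=lambda kv: kv[1])[:keep]
    subsets = []
    for (mm, mi), _ in best:
        mains = tuple(j for j in range(m) if mm[j])
        inter = tuple(p for p, on in zip(pairs, mi) if on)
        subsets.append((mains, inter))
    return subsets


def akaike_weights(aicc_values: np.ndarray) -> np.ndarray:
    """exp(-delta/2) weights, invariant to constant shifts of AICc."""
    a = np.asarray(aicc_values, dtype=float)
    finite = np.isfinite(a)
    w = np.zeros_like(a)
    if finite.any():
        d = a[finite] - a[finite].min()
        ww = np.exp(-d / 2.0)
        w[finite] = ww / ww.sum()
    return w


@dataclass
class ModelEnsemble:
    """Candidate models with bootstrap-smoothed weights and
    model-averaged coefficient inference."""

    models: list[CandidateModel]
    weights: np.ndarray
    term_names: tuple[str, ...]
    avg_coefficients: dict[str, float]
    var_within: dict[str, float]
    var_between: dict[str, float]
    var_total: dict[str, float]
    n_redrawn: int = 0

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Weight-averaged predicted probabilities."""
        X = np.asarray(X, dtype=float)
        p = np.zeros(X.shape[0])
        for w, mdl in zip(self.weights, self.models):
            if w > 0:
                p += w * mdl.predict_proba(X)
        return p


def _stratified_resample(rng, y):
    idx = np.arange(y.size)
    out = []
    for cls in np.unique(y):
        members = idx[y == cls]
        out.append(rng.choice(members, size=members.size, replace=True))
    return np.concatenate(out)


def multimodel_infer(X: np.ndarray, y: np.ndarray,
                     models: list[CandidateModel], B: int = 200,
                     seed: int = 0,
                     names: list[str] | None = None) -> ModelEnsemble:
    """Bootstrap-smoothed multimodel inference over fitted candidates.

    Weights are the across-replicate average of per-replicate Akaike
    weights; coefficients are model-averaged (absent terms count as 0)
    with ``var_total = var_within + var_between`` per coefficient.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    rng = np.random.default_rng(seed)
    weight_acc = np.zeros(len(models))
    used = 0
    redrawn = 0
    attempts = 0
    while used < B:
        attempts += 1
        if attempts > 10 * B:
            raise RuntimeError("too many degenerate bootstrap replicates")
        idx = _stratified_resample(rng, y)
        yb = y[idx]
        if np.unique(yb).size < 2:
            redrawn += 1
            continue
        Xb = X[idx]
        aiccs = np.array([
            _fit_model(Xb, yb, mdl.mains, mdl.interactions, names).aicc
            for mdl in models])
        weight_acc += akaike_weights(aiccs)
        used += 1
    weights = weight_acc / used
    weights = weights / weights.sum()
    return build_ensemble(models, weights, n_redrawn=redrawn)


def build_ensemble(models: list[CandidateModel], weights: np.ndarray,
                   n_redrawn: int = 0) -> ModelEnsemble:
    """Model-average fitted candidates under the given weights."""
    weights = np.asarray(weights, dtype=float)
    # union of term names across models, in first-appearance order
    term_names: list[str] = []
    for mdl in models:
        for t in mdl.terms:
            if t not in term_names:
                term_names.append(t)
    avg = dict.fromkeys(term_names, 0.0)
    vw = dict.fromkeys(term_names, 0.0)
    vb = dict.fromkeys(term_names, 0.0)
    for w, mdl in zip(weights, models):
        for t, b, s in zip(mdl.terms, mdl.coef, mdl.se):
            avg[t] += w * b
            vw[t] += w * s**2
    for w, mdl in zip(weights, models):
        present = dict(zip(mdl.terms, mdl.coef))
        for t in term_names:
            vb[t] += w * (present.get(t, 0.0) - avg[t]) ** 2
    vt = {t: vw[t] + vb[t] for t in term_names}
    return ModelEnsemble(models=models, weights=weights,
                         term_names=tuple(term_names),
                         avg_coefficients=avg, var_within=vw,
                         var_between=vb, var_total=vt,
                         n_redrawn=n_redrawn)
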