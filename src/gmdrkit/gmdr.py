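"""Generalized MDR: score residuals from a covariate-only GLM replace raw
case/control counts, enabling covariate adjustment and continuous traits.

The per-subject score is the raw residual s_i = y_i - mu_i from the null
model ``phenotype ~ intercept + covariates`` (logit link for binary traits,
identity for continuous).  A genotype cell is high-risk iff its mean score
is >= 0.  With a binary trait and no covariates, s_i = y_i - ybar and the
cell criterion reduces exactly to MDR's case:control ratio threshold, so the
two searches coincide cell by cell.

Inside the cross-validation, the null model is re-fit on each training fold
and held-out subjects are scored from that fit; this keeps the score
centering free of test-set information and makes the MDR special case hold
exactly (MDR's ratio threshold is likewise the training-fold ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import Cohort, MISSING
from .mdr import (
    CvReport,
    _Engine,
    _permutation,
    stratified_fold_ids,
    tabulate_and_classify,
)


@dataclass
class ScoreVector:
    """Per-subject score residuals from the covariate-only null model."""

    scores: np.ndarray
    centering: float = 0.0
    trait_kind: str = "binary"


def _design(cov: np.ndarray) -> np.ndarray:
    n = cov.shape[0]
    return np.column_stack([np.ones(n), cov]) if cov.shape[1] else np.ones((n, 1))


def _null_scores(
    y: np.ndarray,
    cov: np.ndarray,
    train: np.ndarray,
    trait: str,
    standardized: bool = False,
) -> np.ndarray:
    """Fit the null GLM on ``train`` rows; return scores for all rows."""
    X = _design(cov)
    if trait == "binary":
        model = sm.GLM(y[train], X[train], family=sm.families.Binomial())
        res = model.fit(maxiter=100)
        if not res.converged:
            raise ValueError(
                "null logistic model did not converge "
                f"(deviance path: {res.fit_history['deviance'][-3:]}); "
                "check for separation in the covariates"
            )
        mu = res.predict(X)
        s = y - mu
        if standardized:
            s = s / np.sqrt(mu * (1.0 - mu))
    else:
        res = sm.OLS(y[train], X[train]).fit()
        mu = X @ res.params
        s = y - mu
        if standardized:
            s = s / np.sqrt(res.scale)
    return s


def score_residuals(
    cohort: Cohort,
    covariate_names: tuple[str, ...] = (),
    standardized: bool = False,
) -> ScoreVector:
    """Whole-cohort score residuals y - mu from the covariate-only null fit."""
    for c in covariate_names:
        if c not in cohort.covariates.columns:
            raise ValueError(f"covariate {c!r} not in cohort")
    cov = cohort.covariates[list(covariate_names)].to_numpy(dtype=float)
    y = cohort.phenotype
    if cohort.trait_kind == "binary":
        cohort.require_binary()
    s = _null_scores(y, cov, np.ones(len(y), dtype=bool), cohort.trait_kind, standardized)
    return ScoreVector(s, 0.0, cohort.trait_kind)


class GmdrClassifier(ClassifierMixin, BaseEstimator):
    """Covariate-adjusted GMDR interaction search (scikit-learn style).

    Same search machinery, reports and attributes as
    :class:`~gmdrkit.mdr.MdrClassifier`; `fit` additionally accepts a
    ``covariates`` array/DataFrame and ``trait`` may be "continuous", in
    which case fold accuracies are balanced accuracies of the HIGH/LOW
    prediction against the dichotomized score (s > 0).
    """

    def __init__(self, k_min: int = 1, k_max: int = 2, n_folds: int = 10,
                 n_permutations: int = 0, random_state: int | None = None,
                 trait: str = "binary", standardized: bool = False):
        self.k_min = k_min
        self.k_max = k_max
        self.n_folds = n_folds
        self.n_permutations = n_permutations
        self.random_state = random_state
        self.trait = trait
        self.standardized = standardized

    def fit(self, X, y, covariates=None):
        X = np.asarray(X, dtype=np.int64)
        if X.ndim != 2 or not np.isin(X, (0, 1, 2, MISSING)).all():
            raise ValueError(f"X must be subjects x loci with codes in {{0,1,2,{MISSING}}}")
        y = np.asarray(y, dtype=float)
        if self.trait == "binary":
            if not set(np.unique(y)) == {0.0, 1.0}:
                raise ValueError("binary trait requires y in {0,1} with both classes")
            self.classes_ = np.array([0, 1])
        else:
            self.classes_ = np.array([0, 1])  # low/high risk group
        if not 1 <= self.k_min <= self.k_max <= X.shape[1]:
            raise ValueError("need 1 <= k_min <= k_max <= n_loci")
        if covariates is None:
            cov = np.zeros((X.shape[0], 0))
        elif isinstance(covariates, pd.DataFrame):
            cov = covariates.to_numpy(dtype=float)
        else:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
        if cov.shape[0] != X.shape[0]:
            raise ValueError("covariates row count does not match X")
        self.n_features_in_ = X.shape[1]

        ss = np.random.SeedSequence(self.random_state)
        rng_folds, rng_perm = (np.random.default_rng(s) for s in ss.spawn(2))
        engine = _Engine(X, list(range(self.k_min, self.k_max + 1)))
        key = np.column_stack([X.astype(float), cov])
        n_folds, trait, std = self.n_folds, self.trait, self.standardized

        def strat_of(yv):
            if trait == "binary":
                return yv.astype(np.int64)
            s_full = _null_scores(yv, cov, np.ones(len(yv), bool), trait, std)
            return (s_full > 0).astype(np.int64)

        def fold_data_of(yv, fold_ids):
            out = []
            for f in range(n_folds):
                s = _null_scores(yv, cov, fold_ids != f, trait, std)
                eval01 = yv.astype(np.int64) if trait == "binary" else (s > 0).astype(np.int64)
                out.append((s, eval01))
            return out

        def run_once(y_perm, rng):
            fid = stratified_fold_ids(strat_of(y_perm), key, n_folds, rng)
            _, best = engine.search(fid, fold_data_of(y_perm, fid))
            return best

        fold_ids = stratified_fold_ids(strat_of(y), key, n_folds, rng_folds)
        self.fold_ids_ = fold_ids
        self.reports_, self.best_report_ = engine.search(fold_ids, fold_data_of(y, fold_ids))
        self.best_loci_ = self.best_report_.chosen_model
        sv = _null_scores(y, cov, np.ones(len(y), bool), trait, std)
        self.scores_ = sv
        self.partition_ = tabulate_and_classify(X, y, self.best_loci_, scores=sv)
        if self.n_permutations > 0:
            p_cvc, p_ba = _permutation(
                engine, y, run_once, self.best_report_, self.n_permutations, rng_perm
            )
            self.permutation_p_ = p_cvc
            self.permutation_p_test_ba_ = p_ba
            self.best_report_.perm_p = p_cvc
            self.best_report_.perm_p_test_ba = p_ba
        return self

    def predict(self, X):
        check_is_fitted(self, "partition_")
        return self.partition_.predict(np.asarray(X, dtype=np.int64)).astype(np.int64)


def run_gmdr_search(
    cohort: Cohort,
    covariate_names: tuple[str, ...] = (),
    k_min: int = 1,
    k_max: int = 2,
    folds: int = 10,
    seed: int | None = None,
    permutations: int = 0,
    standardized: bool = False,
) -> tuple[list[CvReport], CvReport]:
    """Covariate-adjusted GMDR search over a cohort; see GmdrClassifier."""
    for c in covariate_names:
        if c not in cohort.covariates.columns:
            raise ValueError(f"covariate {c!r} not in cohort")
    est = GmdrClassifier(
        k_min=k_min, k_max=k_max, n_folds=folds, n_permutations=permutations,
        random_state=seed, trait=cohort.trait_kind, standardized=standardized,
    )
    cov = cohort.covariates[list(covariate_names)] if covariate_names else None
    est.fit(cohort.genotypes, cohort.phenotype, covariates=cov)
    return est.reports_, est.best_report_
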