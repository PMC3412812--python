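"""Multifactor dimensionality reduction (MDR) search.

Exhaustive k-locus enumeration with stratified 10-fold cross-validation.
Each multi-locus genotype cell is labeled high- or low-risk by comparing its
case:control ratio with the training-set ratio T (inclusive: ratio >= T is
high risk); the resulting one-dimensional attribute is scored by balanced
accuracy.  Model choice within a fold maximizes training balanced accuracy;
across folds the modal best tuple is reported with its cross-validation
consistency (CVC), the exact binomial sign test of the fold testing
accuracies, and an optional permutation p-value.

The same engine runs in "score" mode (cell high-risk iff its mean score
residual is >= 0), which is what the GMDR front end uses; with a binary
trait and no covariates the two criteria coincide cell by cell, making MDR
an exact special case.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import Cohort, MISSING

HIGH, LOW, EMPTY = "HIGH", "LOW", "EMPTY"


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def balanced_accuracy(y_true: np.ndarray, pred_high: np.ndarray) -> float:
    """(sensitivity + specificity) / 2 of a high/low-risk prediction."""
    y = np.asarray(y_true).astype(bool)
    p = np.asarray(pred_high).astype(bool)
    if not y.any() or y.all():
        raise ValueError("evaluation set needs at least one case and one control")
    sens = p[y].mean()
    spec = (~p[~y]).mean()
    return float((sens + spec) / 2.0)


def sign_test_p(sign_count: int, n_folds: int = 10) -> float:
    """Exact one-sided binomial tail P(X >= sign_count), X ~ Bin(n_folds, 1/2)."""
    if not 0 <= sign_count <= n_folds:
        raise ValueError(f"sign_count {sign_count} outside 0..{n_folds}")
    return float(stats.binom.sf(sign_count - 1, n_folds, 0.5))


@dataclass
class CellPartition:
    """A locus subset with its genotype cells, counts/score sums and labels.

    In count mode ``cells`` maps each genotype-code tuple to
    (n_cases, n_controls) and ``threshold`` is the training case:control
    ratio T; in score mode it maps to (score_sum, n_subjects) and the
    threshold is 0.  Unobserved cells are labeled EMPTY (and predict LOW).
    """

    loci: tuple[int, ...]
    cells: dict[tuple[int, ...], tuple[float, float]]
    threshold: float
    labels: dict[tuple[int, ...], str]
    mode: str = "count"

    def predict(self, genotypes: np.ndarray) -> np.ndarray:
        """High-risk membership of new subjects (EMPTY/unseen -> low risk)."""
        G = np.asarray(genotypes)
        out = np.zeros(G.shape[0], dtype=bool)
        for i in range(G.shape[0]):
            cell = tuple(int(g) for g in G[i, list(self.loci)])
            out[i] = self.labels.get(cell) == HIGH
        return out


def tabulate_and_classify(
    genotypes: np.ndarray,
    y: np.ndarray,
    loci: tuple[int, ...],
    scores: np.ndarray | None = None,
) -> CellPartition:
    """Tabulate the genotype cells of ``loci`` and label each high/low risk.

    Count mode (``scores`` is None): a cell is HIGH iff its case:control
    ratio is >= T = total cases / total controls of the training subjects
    (a cell with cases but no controls is HIGH).  Score mode: HIGH iff the
    cell's mean score is >= 0.  Subjects missing a genotype at ``loci`` are
    excluded.
    """
    G = np.asarray(genotypes)
    loci = tuple(loci)
    sub = G[:, list(loci)]
    ok = (sub != MISSING).all(axis=1)
    sub = sub[ok]
    if scores is None:
        yb = np.asarray(y).astype(int)[ok]
        n_cases, n_controls = int(yb.sum()), int((1 - yb).sum())
        if n_cases == 0 or n_controls == 0:
            raise ValueError("training data must contain both cases and controls")
        threshold = n_cases / n_controls
    else:
        scores = np.asarray(scores, dtype=float)[ok]
        threshold = 0.0
    cells: dict[tuple, tuple] = {}
    labels: dict[tuple, str] = {}
    for combo in itertools.product(range(3), repeat=len(loci)):
        in_cell = (sub == np.array(combo)).all(axis=1)
        n = int(in_cell.sum())
        if scores is None:
            c = int(yb[in_cell].sum())
            d = n - c
            cells[combo] = (c, d)
            if n == 0:
                labels[combo] = EMPTY
            elif d == 0:
                labels[combo] = HIGH if c > 0 else EMPTY
            else:
                labels[combo] = HIGH if c / d >= threshold else LOW
        else:
            s = float(scores[in_cell].sum())
            cells[combo] = (s, n)
            tol = 1e-9 * max(1.0, float(np.abs(scores).max()))
            labels[combo] = EMPTY if n == 0 else (HIGH if s >= -tol else LOW)
    return CellPartition(loci, cells, threshold, labels,
                         mode="count" if scores is None else "score")


# ---------------------------------------------------------------------------
# Cross-validated exhaustive search
# ---------------------------------------------------------------------------


@dataclass
class CvReport:
    """Per-k summary of the cross-validated exhaustive search."""

    k: int
    best_model_per_fold: list[tuple[int, ...]]
    chosen_model: tuple[int, ...]
    cvc: int
    train_ba: float
    test_ba: float
    fold_train_ba: list[float]
    fold_test_ba: list[float]
    sign_count: int
    sign_p: float
    perm_p: float | None = None
    perm_p_test_ba: float | None = None

    def to_dict(self, snp_ids: list[str] | None = None) -> dict:
        name = (lambda t: [snp_ids[i] for i in t]) if snp_ids else (lambda t: list(t))
        return {
            "k": self.k,
            "chosen_model": name(self.chosen_model),
            "cvc": self.cvc,
            "train_ba": round(self.train_ba, 6),
            "test_ba": round(self.test_ba, 6),
            "sign_count": self.sign_count,
            "sign_p": round(self.sign_p, 6),
            "best_model_per_fold": [name(t) for t in self.best_model_per_fold],
            "perm_p": self.perm_p,
            "perm_p_test_ba": self.perm_p_test_ba,
        }


def stratified_fold_ids(
    strat: np.ndarray,
    key: np.ndarray,
    n_folds: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stratified fold assignment that is invariant to subject order.

    Subjects are put in a canonical order (lexicographic on the columns of
    ``key``) before folds are dealt, so permuting the input rows permutes
    the assignment with them.
    """
    n = len(strat)
    order = np.lexsort(np.column_stack([key, strat]).T[::-1])
    fold = np.empty(n, dtype=np.int64)
    for cls in np.unique(strat):
        idx = order[strat[order] == cls]
        fold[idx] = rng.permutation(len(idx)) % n_folds
    return fold


class _Engine:
    """Precomputed genotype-cell indices for every locus tuple in the k range."""

    def __init__(self, G: np.ndarray, k_values: list[int]):
        self.G = np.asarray(G)
        n, m = self.G.shape
        self.n, self.m = n, m
        self.groups: list[tuple[int, list[tuple[int, ...]], np.ndarray, int]] = []
        for k in k_values:
            combos = list(itertools.combinations(range(m), k))
            powers = 3 ** np.arange(k)
            cells = np.empty((len(combos), n), dtype=np.int64)
            for i, c in enumerate(combos):
                sub = self.G[:, list(c)]
                idx = sub @ powers
                idx[(sub == MISSING).any(axis=1)] = -1
                cells[i] = idx
            self.groups.append((k, combos, cells, 3 ** k))

    def search(
        self,
        fold_ids: np.ndarray,
        fold_data: list[tuple[np.ndarray, np.ndarray]],
    ) -> tuple[list[CvReport], CvReport]:
        """Run the exhaustive CV search.

        ``fold_data[f]`` is ``(w, eval01)`` for fold f: per-subject labeling
        weights (cell HIGH iff its training-weight sum is >= 0) and the 0/1
        outcome the balanced accuracy is computed against.
        """
        n_folds = len(fold_data)
        reports = []
        for k, combos, cells, ncells in self.groups:
            tr_ba = np.empty((len(combos), n_folds))
            te_ba = np.empty((len(combos), n_folds))
            for f in range(n_folds):
                w, eval01 = fold_data[f]
                ev = eval01.astype(bool)
                # ratio-threshold ties label HIGH; the tolerance keeps that
                # inclusive convention stable under GLM-fit round-off in
                # score mode (exact zeros are integer arithmetic in count mode)
                tol = 1e-9 * max(1.0, float(np.abs(w).max()))
                for i in range(len(combos)):
                    cidx = cells[i]
                    valid = cidx >= 0
                    tr = (fold_ids != f) & valid
                    te = (fold_ids == f) & valid
                    sums = np.bincount(cidx[tr], weights=w[tr], minlength=ncells)
                    cnt = np.bincount(cidx[tr], minlength=ncells)
                    high = (sums >= -tol) & (cnt > 0)
                    tr_ba[i, f] = _ba(ev[tr], high[cidx[tr]])
                    te_ba[i, f] = _ba(ev[te], high[cidx[te]])
            best_idx = np.argmax(tr_ba, axis=0)  # first max: lexicographic tie-break
            best_per_fold = [combos[i] for i in best_idx]
            tally = Counter(best_per_fold)
            # ties on CVC are broken on training data only (mean training BA,
            # then lexicographic), so the reported testing accuracies and the
            # sign test stay untouched by model choice
            candidates = sorted(
                tally,
                key=lambda t: (-tally[t], -float(tr_ba[combos.index(t)].mean()), t),
            )
            chosen = candidates[0]
            ci = combos.index(chosen)
            fold_test = te_ba[ci].tolist()
            sign_count = int(np.sum(np.array(fold_test) > 0.5))
            reports.append(
                CvReport(
                    k=k,
                    best_model_per_fold=best_per_fold,
                    chosen_model=chosen,
                    cvc=tally[chosen],
                    train_ba=float(tr_ba[ci].mean()),
                    test_ba=float(te_ba[ci].mean()),
                    fold_train_ba=tr_ba[ci].tolist(),
                    fold_test_ba=fold_test,
                    sign_count=sign_count,
                    sign_p=sign_test_p(sign_count, n_folds),
                )
            )
        best = max(reports, key=lambda r: (r.test_ba, r.cvc, -r.k))
        return reports, best


def _ba(y_bool: np.ndarray, pred: np.ndarray) -> float:
    if not y_bool.any() or y_bool.all():
        raise ValueError(
            "a cross-validation fold lacks one outcome class; use fewer folds"
        )
    return ((pred[y_bool].mean()) + ((~pred[~y_bool]).mean())) / 2.0


def _count_fold_data(y01: np.ndarray, fold_ids: np.ndarray, n_folds: int):
    """MDR weights: cell sum of w is >= 0 iff cell cases/controls >= T(train)."""
    out = []
    for f in range(n_folds):
        tr = fold_ids != f
        r = int(y01[tr].sum())
        s = int((1 - y01[tr]).sum())
        if r == 0 or s == 0:
            raise ValueError("a training split lacks cases or controls; use fewer folds")
        w = np.where(y01 == 1, float(s), -float(r))
        out.append((w, y01))
    return out


def _permutation(
    engine: _Engine,
    y: np.ndarray,
    run_once,
    observed: CvReport,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Permutation p-values for the overall best model.

    The phenotype vector is permuted (detaching it from genotypes and
    covariates) and the full search re-run.  Primary statistic: CVC with
    testing-BA tie-break; a testing-BA-only p is returned alongside.
    p = (r + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs = (observed.cvc, observed.test_ba)
    r_cvc = 0
    r_ba = 0
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        best = run_once(y_perm, rng)
        if (best.cvc, best.test_ba) >= obs:
            r_cvc += 1
        if best.test_ba >= observed.test_ba:
            r_ba += 1
    return (r_cvc + 1) / (n_perm + 1), (r_ba + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------


class MdrClassifier(ClassifierMixin, BaseEstimator):
    """Exhaustive MDR interaction search as a scikit-learn classifier.

    Parameters
    ----------
    k_min, k_max : interaction orders searched (all locus tuples of each size).
    n_folds : stratified cross-validation folds (default 10).
    n_permutations : if > 0, permutation p-values for the best model.
    random_state : seed controlling fold assignment and permutations.

    Attributes (after fit)
    ----------------------
    reports_ : list of CvReport, one per k.
    best_report_ : the overall best (highest testing BA, ties by CVC then
        smaller k).
    best_loci_ : locus tuple of the best model.
    partition_ : CellPartition of the best model re-tabulated on all data
        (used by :meth:`predict`).
    permutation_p_, permutation_p_test_ba_ : permutation p-values (if run).
    """

    def __init__(self, k_min: int = 1, k_max: int = 2, n_folds: int = 10,
                 n_permutations: int = 0, random_state: int | None = None):
        self.k_min = k_min
        self.k_max = k_max
        self.n_folds = n_folds
        self.n_permutations = n_permutations
        self.random_state = random_state

    def _validate(self, X, y):
        X = np.asarray(X, dtype=np.int64)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (subjects x loci)")
        if not np.isin(X, (0, 1, 2, MISSING)).all():
            raise ValueError(f"genotype codes must be in {{0,1,2,{MISSING}}}")
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2 or not set(classes) <= {0, 1}:
            raise ValueError("y must be binary 0/1 with both classes present")
        if not 1 <= self.k_min <= self.k_max <= X.shape[1]:
            raise ValueError("need 1 <= k_min <= k_max <= n_loci")
        return X, y.astype(np.int64), classes

    def fit(self, X, y):
        X, y, self.classes_ = self._validate(X, y)
        self.n_features_in_ = X.shape[1]
        ss = np.random.SeedSequence(self.random_state)
        rng_folds, rng_perm = (np.random.default_rng(s) for s in ss.spawn(2))
        engine = _Engine(X, list(range(self.k_min, self.k_max + 1)))

        def run_once(y01, rng):
            fid = stratified_fold_ids(y01, X, self.n_folds, rng)
            _, best = engine.search(fid, _count_fold_data(y01, fid, self.n_folds))
            return best

        fold_ids = stratified_fold_ids(y, X, self.n_folds, rng_folds)
        self.reports_, self.best_report_ = engine.search(
            fold_ids, _count_fold_data(y, fold_ids, self.n_folds)
        )
        self.best_loci_ = self.best_report_.chosen_model
        self.fold_ids_ = fold_ids
        self.partition_ = tabulate_and_classify(X, y, self.best_loci_)
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
        X = np.asarray(X, dtype=np.int64)
        return self.partition_.predict(X).astype(np.int64)


# ---------------------------------------------------------------------------
# Cohort-level wrappers
# ---------------------------------------------------------------------------


def run_mdr_search(
    cohort: Cohort,
    k_min: int = 1,
    k_max: int = 2,
    folds: int = 10,
    seed: int | None = None,
    permutations: int = 0,
) -> tuple[list[CvReport], CvReport]:
    """Exhaustive MDR search over a binary-trait cohort; see MdrClassifier."""
    y = cohort.require_binary()
    est = MdrClassifier(k_min=k_min, k_max=k_max, n_folds=folds,
                        n_permutations=permutations, random_state=seed)
    est.fit(cohort.genotypes, y)
    return est.reports_, est.best_report_


def permutation_pvalue(
    cohort: Cohort,
    k_min: int = 1,
    k_max: int = 2,
    folds: int = 10,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, CvReport]:
    """Permutation p-value (CVC statistic, testing-BA tie-break) for the best
    MDR model of a cohort."""
    est = MdrClassifier(k_min=k_min, k_max=k_max, n_folds=folds,
                        n_permutations=n_perm, random_state=seed)
    est.fit(cohort.genotypes, cohort.require_binary())
    return est.permutation_p_, est.best_report_
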