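import itertools

import numpy as np
import pytest
from sklearn.metrics import balanced_accuracy_score

from gmdrkit.mdr import (
    EMPTY,
    HIGH,
    LOW,
    MdrClassifier,
    balanced_accuracy,
    run_mdr_search,
    sign_test_p,
    tabulate_and_classify,
)
from gmdrkit.simulate import (
    PenetranceSpec,
    SimulationConfig,
    simulate_cohort,
    study_cohort,
)
from conftest import make_random_cohort


def brute_force_labels(G, y, loci):
    """Independent oracle: per-cell case/control tally via explicit loops."""
    cases = {}
    controls = {}
    for i in range(len(y)):
        cell = tuple(int(g) for g in G[i, list(loci)])
        if any(g < 0 for g in cell):
            continue
        if y[i] == 1:
            cases[cell] = cases.get(cell, 0) + 1
        else:
            controls[cell] = controls.get(cell, 0) + 1
    t_cases = sum(cases.values())
    t_controls = sum(controls.values())
    labels = {}
    for cell in itertools.product(range(3), repeat=len(loci)):
        c, d = cases.get(cell, 0), controls.get(cell, 0)
        if c + d == 0:
            labels[cell] = EMPTY
        elif d == 0:
            labels[cell] = HIGH
        else:
            labels[cell] = HIGH if c / d >= t_cases / t_controls else LOW
    return labels


class TestTabulateAndClassify:
    def test_study_size_threshold_and_high_cell(self):
        # 324 cases / 373 controls -> T = 324/373; a 3-case/1-control cell is HIGH
        y = np.array([1] * 324 + [0] * 373)
        G = np.zeros((697, 1), dtype=int)
        G[:3, 0] = 2
        G[324, 0] = 2  # cell "2": 3 cases, 1 control
        part = tabulate_and_classify(G, y, (0,))
        assert part.threshold == pytest.approx(324 / 373)
        assert part.cells[(2,)] == (3, 1)
        assert part.labels[(2,)] == HIGH

    def test_ratio_equal_to_threshold_is_high(self):
        # T = 1 and a balanced cell: the inclusive convention labels it HIGH
        y = np.array([1, 0, 1, 0])
        G = np.array([[0], [0], [1], [1]])
        part = tabulate_and_classify(G, y, (0,))
        assert part.threshold == 1.0
        assert part.labels[(0,)] == HIGH and part.labels[(1,)] == HIGH

    def test_case_only_cell_high_and_unseen_empty(self):
        y = np.array([1, 1, 0, 0])
        G = np.array([[0], [0], [1], [1]])
        part = tabulate_and_classify(G, y, (0,))
        assert part.labels[(0,)] == HIGH and part.labels[(1,)] == LOW
        assert part.labels[(2,)] == EMPTY
        assert not part.predict(np.array([[2]]))[0]  # EMPTY predicts LOW

    def test_requires_both_classes(self):
        with pytest.raises(ValueError, match="cases and controls"):
            tabulate_and_classify(np.array([[0], [1]]), np.array([1, 1]), (0,))

    def test_matches_brute_force_oracle_on_random_data(self, rng):
        for _ in range(200):
            n = int(rng.integers(10, 51))
            m = int(rng.integers(1, 4))
            G = rng.integers(0, 3, size=(n, m))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            loci = tuple(sorted(rng.choice(m, size=int(rng.integers(1, m + 1)),
                                           replace=False).tolist()))
            part = tabulate_and_classify(G, y, loci)
            assert part.labels == brute_force_labels(G, y, loci)


class TestBalancedAccuracy:
    def test_perfect_and_degenerate_predictions(self):
        y = np.array([1, 1, 0, 0])
        assert balanced_accuracy(y, np.array([1, 1, 0, 0])) == 1.0
        assert balanced_accuracy(y, np.array([1, 1, 1, 1])) == 0.5

    def test_hand_worked_confusion_matrix(self):
        # TP=2, FN=1, TN=2, FP=1 -> (2/3 + 2/3)/2
        y = np.array([1, 1, 1, 0, 0, 0])
        pred = np.array([1, 1, 0, 0, 0, 1])
        assert balanced_accuracy(y, pred) == pytest.approx(2 / 3)

    def test_matches_sklearn_on_random_data(self, rng):
        for _ in range(100):
            y = rng.integers(0, 2, 30)
            pred = rng.integers(0, 2, 30)
            if y.min() == y.max():
                continue
            assert balanced_accuracy(y, pred) == pytest.approx(
                balanced_accuracy_score(y, pred)
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy(np.array([1, 1]), np.array([1, 0]))


class TestSignTest:
    @pytest.mark.parametrize(
        "count,p4dp",
        [(9, 0.0107), (7, 0.1719), (5, 0.6230), (6, 0.3770), (4, 0.8281), (10, 0.0010)],
    )
    def test_binomial_tail_closed_form(self, count, p4dp):
        assert round(sign_test_p(count), 4) == p4dp

    def test_boundaries(self):
        assert sign_test_p(0) == 1.0
        assert sign_test_p(10) == pytest.approx(1 / 1024)
        with pytest.raises(ValueError):
            sign_test_p(11)


class TestSearch:
    def test_recovers_generating_pair(self):
        cohort = study_cohort(seed=13)
        reports, best = run_mdr_search(cohort, 2, 2, seed=13)
        assert reports[0].chosen_model == (3, 5)
        assert reports[0].cvc >= 8

    def test_strong_marginal_locus_found_at_k1(self):
        spec = PenetranceSpec(baseline_logit=-1.6,
                              per_locus_betas={2: (0.8, "allelic")})
        config = SimulationConfig(n_cases=300, n_controls=300,
                                  mafs=(0.3, 0.3, 0.3, 0.3), seed=14)
        cohort = simulate_cohort(spec, config)
        reports, _ = run_mdr_search(cohort, 1, 1, seed=14)
        assert reports[0].chosen_model == (2,)

    def test_training_ba_at_least_half(self, rng):
        # ratio-threshold labeling matches each cell's majority side relative
        # to the prior, so training BA >= 0.5 always
        for i in range(20):
            cohort = make_random_cohort(rng, n=80, m=4)
            reports, _ = run_mdr_search(cohort, 1, 2, seed=i)
            for r in reports:
                assert all(ba >= 0.5 for ba in r.fold_train_ba)

    def test_fold_without_both_classes_errors(self):
        y = np.concatenate([np.ones(3), np.zeros(57)])
        G = np.random.default_rng(0).integers(0, 3, (60, 2))
        est = MdrClassifier(1, 1, n_folds=10, random_state=0)
        with pytest.raises(ValueError, match="folds"):
            est.fit(G, y)

    def test_subject_and_locus_order_invariance(self, rng):
        cohort = make_random_cohort(rng, n=120, m=4)
        reports, best = run_mdr_search(cohort, 1, 2, seed=5)
        perm = rng.permutation(cohort.n_subjects)
        cohort2 = make_random_cohort(rng, n=120, m=4)
        cohort2.genotypes = cohort.genotypes[perm]
        cohort2.phenotype = cohort.phenotype[perm]
        cohort2.covariates = cohort.covariates.iloc[perm].reset_index(drop=True)
        reports2, best2 = run_mdr_search(cohort2, 1, 2, seed=5)
        for r1, r2 in zip(reports, reports2):
            assert r1.chosen_model == r2.chosen_model
            assert r1.cvc == r2.cvc
            assert np.allclose(sorted(r1.fold_test_ba), sorted(r2.fold_test_ba))
        assert best.chosen_model == best2.chosen_model

    def test_end_to_end_determinism(self):
        cohort = study_cohort(seed=21)
        r1, b1 = run_mdr_search(cohort, 1, 3, seed=7, permutations=20)
        r2, b2 = run_mdr_search(cohort, 1, 3, seed=7, permutations=20)
        for a, b in zip(r1, r2):
            assert a == b
        assert b1.perm_p == b2.perm_p

    def test_sklearn_estimator_contract(self):
        cohort = study_cohort(seed=22)
        est = MdrClassifier(k_min=2, k_max=2, random_state=0)
        est.fit(cohort.genotypes, cohort.phenotype.astype(int))
        assert est.best_loci_ == est.best_report_.chosen_model
        pred = est.predict(cohort.genotypes)
        assert set(np.unique(pred)) <= {0, 1}
        assert est.get_params()["k_max"] == 2
        cloned = est.set_params(k_max=2)
        assert cloned is est


class TestPermutation:
    def test_add_one_estimator_and_preconditions(self):
        cohort = study_cohort(seed=23, contrast=0.12)
        est = MdrClassifier(2, 2, n_permutations=19, random_state=3)
        est.fit(cohort.genotypes, cohort.phenotype.astype(int))
        # p = (r+1)/(n_perm+1) lives on the grid {1/20, ..., 20/20}
        assert est.permutation_p_ in [k / 20 for k in range(1, 21)]
        # strong signal: observed (cvc, test BA) should beat most permutations
        assert est.permutation_p_ <= 0.2
        with pytest.raises(ValueError, match="n_perm"):
            from gmdrkit.mdr import _permutation

            _permutation(None, None, None, None, 0, np.random.default_rng(0))

    def test_null_permutation_p_not_small_typically(self, rng):
        # pre-permuted phenotype: p should rarely be extreme
        small = 0
        reps = 30
        for i in range(reps):
            cohort = make_random_cohort(rng, n=200, m=3)
            est = MdrClassifier(2, 2, n_permutations=39, random_state=i)
            est.fit(cohort.genotypes, cohort.phenotype.astype(int))
            small += est.permutation_p_ <= 0.05
        assert small <= 4
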