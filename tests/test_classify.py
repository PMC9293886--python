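"""MCC metrics, SVM training/prediction, baselines and thresholds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from puncta.classify import (
    ConfusionMatrix,
    FocusSVC,
    cv_mcc,
    default_grids,
    grid_search,
    mcc,
    mcc_labels,
    predict,
    random_quantifier,
    threshold_classify,
    train,
)
from puncta.features import FEATURE_NAMES


class TestMCC:
    def test_perfect_classification(self):
        assert mcc(ConfusionMatrix(TP=5, TN=5, FP=0, FN=0)) == 1.0

    def test_perfect_misclassification(self):
        assert mcc(ConfusionMatrix(TP=0, TN=0, FP=5, FN=5)) == -1.0

    def test_hand_evaluated_formula(self):
        # (3*4 - 2*1) / sqrt(5*4*6*5) = 10 / sqrt(600)
        expected = 10 / np.sqrt(600)
        assert mcc(ConfusionMatrix(TP=3, TN=4, FP=2, FN=1)) == pytest.approx(expected)
        assert expected == pytest.approx(0.408248, abs=1e-6)

    def test_zero_denominator_convention(self):
        assert mcc(ConfusionMatrix(TP=10, TN=0, FP=0, FN=0)) == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            mcc(ConfusionMatrix(0, 0, 0, 0))

    @given(
        tp=st.integers(0, 50),
        tn=st.integers(0, 50),
        fp=st.integers(0, 50),
        fn=st.integers(0, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_class_swap_symmetry(self, tp, tn, fp, fn):
        """Swapping the two classes swaps TP<->TN and FP<->FN, same MCC."""
        if tp + tn + fp + fn == 0:
            return
        a = mcc(ConfusionMatrix(tp, tn, fp, fn))
        b = mcc(ConfusionMatrix(tn, tp, fn, fp))
        assert a == pytest.approx(b, abs=1e-12)

    def test_from_labels(self):
        truth = np.array([1, 1, 0, 0, 1])
        pred = np.array([1, 0, 0, 1, 1])
        cm = ConfusionMatrix.from_labels(truth, pred)
        assert (cm.TP, cm.TN, cm.FP, cm.FN) == (2, 1, 1, 1)


def toy_separable(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, (n, 2))
    y = (X[:, 0] + X[:, 1] > 1.0).astype(int)
    X[y == 1] += 0.3  # margin
    return X, y


class TestTrainPredict:
    def test_separable_training_mcc_is_one(self):
        X, y = toy_separable()
        model = train(X, y)
        assert mcc_labels(y, model.predict(X)) == 1.0

    def test_deterministic(self):
        X, y = toy_separable(seed=3)
        p1 = train(X, y).predict(X)
        p2 = train(X, y).predict(X)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected_with_guidance(self):
        X = np.random.default_rng(0).uniform(size=(10, 3))
        with pytest.raises(ValueError, match="threshold"):
            train(X, np.ones(10, dtype=int))

    def test_dimension_mismatch_rejected(self):
        X, y = toy_separable()
        model = train(X, y)
        with pytest.raises(ValueError, match="dimension"):
            model.predict(np.zeros((4, 5)))

    def test_json_round_trip_predictions(self, tmp_path):
        X, y = toy_separable(seed=5)
        model = train(X, y)
        path = tmp_path / "model.json"
        model.save(path)
        reloaded = FocusSVC.load(path)
        assert np.array_equal(model.predict(X), reloaded.predict(X))

    def test_override_flips_exactly_one(self):
        X, y = toy_separable()
        model = train(X, y)
        base, _ = predict(model, X)
        flipped, _ = predict(model, X, overrides={3: 1 - base[3]})
        diff = np.flatnonzero(base != flipped)
        assert diff.tolist() == [3]

    def test_batching_invariance(self):
        X, y = toy_separable(seed=7)
        model = train(X, y)
        whole = model.predict(X)
        parts = np.concatenate([model.predict(X[:20]), model.predict(X[20:40]), model.predict(X[40:])])
        assert np.array_equal(whole, parts)

    def test_per_cell_summary(self):
        X, y = toy_separable()
        model = train(X, y)
        labels, summary = predict(model, X, cell_ids=np.repeat([0, 1, 2], 20))
        assert sum(summary.values()) == labels.sum()


class TestCVMCC:
    def test_rule_labeled_candidates_are_learnable(self, labeled_dataset):
        X, y, _ = labeled_dataset
        assert cv_mcc(X, y, k=6) >= 0.95

    def test_permuted_labels_score_near_zero(self, labeled_dataset):
        X, y, _ = labeled_dataset
        y_perm = np.random.default_rng(0).permutation(y)
        assert abs(cv_mcc(X, y_perm, k=6)) < 0.15

    def test_too_many_folds_rejected(self):
        X, y = toy_separable(n=10)
        with pytest.raises(ValueError):
            cv_mcc(X, y, k=11)

    def test_leave_one_out_rejected_single_class_folds(self):
        X, y = toy_separable(n=12)
        with pytest.raises(ValueError):
            cv_mcc(X, y, k=12)

    def test_generalization_gap_non_negative_on_average(self):
        gaps = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.uniform(0, 1, (80, 4))
            y = (X[:, 0] > 0.5).astype(int) ^ (rng.random(80) < 0.1).astype(int)
            model = train(X, y)
            train_mcc = mcc_labels(y, model.predict(X))
            gaps.append(train_mcc - cv_mcc(X, y, k=6, seed=seed))
        assert np.mean(gaps) >= 0


class TestGridSearch:
    def test_singleton_grid_returned(self):
        X, y = toy_separable()
        C, gamma, _ = grid_search(X, y, C_grid=[2.0], gamma_grid=[0.5])
        assert (C, gamma) == (2.0, 0.5)

    def test_three_by_three_equals_brute_force(self, labeled_dataset):
        X, y, _ = labeled_dataset
        X, y = X[:240], y[:240]
        C_grid, g_grid = [0.1, 1.0, 10.0], [0.01, 0.1, 1.0]
        C, gamma, score = grid_search(X, y, C_grid=C_grid, gamma_grid=g_grid)
        # brute-force oracle: evaluate every pair in a plain double loop
        best = None
        for Cb in C_grid:
            for gb in g_grid:
                s = cv_mcc(X, y, k=6, C=Cb, gamma=gb)
                if best is None or s > best[2] + 1e-12:
                    best = (Cb, gb, s)
        assert (C, gamma) == best[:2]
        assert score == pytest.approx(best[2])

    def test_default_grid_ranges(self):
        C_grid, g_grid = default_grids()
        assert C_grid[0] == pytest.approx(1e-3) and C_grid[-1] == pytest.approx(1e3)
        assert g_grid[0] == pytest.approx(1e-8) and g_grid[-1] == pytest.approx(10.0)

    def test_optimum_close_to_default_on_easy_data(self, labeled_dataset):
        # hyperparameter search gives only minor gains on separable data
        X, y, _ = labeled_dataset
        X, y = X[:240], y[:240]
        default_score = cv_mcc(X, y, k=6)
        _, _, best_score = grid_search(
            X, y, C_grid=[0.1, 1.0, 10.0], gamma_grid=[0.01, 0.1, 1.0]
        )
        assert best_score >= default_score - 1e-9
        assert best_score - default_score < 0.05


class TestRandomQuantifier:
    def test_null_distribution_near_zero(self):
        rng = np.random.default_rng(4)
        reference = [rng.integers(0, 2, 13) for _ in range(55)]
        score = random_quantifier(reference, n_reps=50, seed=1)
        assert abs(score) < 0.1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        reference = [rng.integers(0, 2, 10) for _ in range(20)]
        a = random_quantifier(reference, n_reps=50, seed=9)
        b = random_quantifier(reference, n_reps=50, seed=9)
        assert a == b

    def test_reference_selecting_everything_is_guarded(self):
        reference = [np.ones(5, dtype=int) for _ in range(10)]
        # every repetition reproduces the reference exactly: single-class
        # comparison, scored 0 by the zero-denominator convention
        assert random_quantifier(reference, n_reps=10, seed=0) == 0.0


class TestThresholdClassify:
    def test_no_bounds_labels_everything_positive(self):
        X = np.random.default_rng(0).uniform(size=(9, 12))
        assert threshold_classify(X, {}).tolist() == [1] * 9

    def test_bright_peak_bound_selects_by_construction(self):
        X = np.zeros((6, 12))
        X[:, 0] = [0.95, 0.2, 0.91, 0.5, 0.99, 0.1]
        labels = threshold_classify(X, {"f1_max": (0.9, None)})
        assert labels.tolist() == [1, 0, 1, 0, 1, 0]

    def test_matches_per_candidate_loop_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(50, 12))
        bounds = {"f1_max": (0.3, 0.9), "f2_area": (None, 0.7), "f8_brightness_index": (0.5, None)}
        labels = threshold_classify(X, bounds)
        for i in range(50):  # brute-force conjunction check
            row = dict(zip(FEATURE_NAMES, X[i]))
            expected = (
                0.3 <= row["f1_max"] <= 0.9
                and row["f2_area"] <= 0.7
                and row["f8_brightness_index"] >= 0.5
            )
            assert labels[i] == int(expected)

    def test_invalid_bounds_rejected(self):
        X = np.zeros((3, 12))
        with pytest.raises(ValueError):
            threshold_classify(X, {"f1_max": (0.9, 0.1)})
        with pytest.raises(KeyError):
            threshold_classify(X, {"nope": (0, 1)})
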