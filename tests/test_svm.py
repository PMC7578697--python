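"""Linear SVM training, metrics identities, and cross-validation contracts."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from citnirs.svm import (
    ConfusionMatrix,
    CVConfig,
    LinearModel,
    compare_metric_distributions,
    confusion,
    decision_function,
    fold_assignments,
    metrics,
    predict,
    repeated_kfold,
    svm_objective,
    train_linear_svm,
)

from qp_oracle import brute_force_svm


class TestTrainLinearSvm:
    def test_symmetric_two_point_problem(self):
        X = np.array([[1.0], [-1.0]])
        y = np.array([1.0, -1.0])
        model = train_linear_svm(X, y, C=1e6)
        assert model.w[0] == pytest.approx(1.0, abs=1e-5)
        assert model.b == pytest.approx(0.0, abs=1e-5)

    def test_separable_margin_constraints_hold(self, rng):
        X = np.vstack([rng.normal(3, 0.5, (10, 2)), rng.normal(-3, 0.5, (10, 2))])
        y = np.r_[np.ones(10), -np.ones(10)]
        model = train_linear_svm(X, y, C=1e4)
        assert np.all(y * decision_function(model, X) >= 1 - 1e-6)
        assert np.all(predict(model, X) == y)

    @pytest.mark.parametrize("seed", range(6))
    def test_objective_matches_brute_force_qp(self, seed):
        """SMO objective agrees with active-set enumeration on tiny instances."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        X = rng.normal(0, 1, (n, 2))
        y = np.sign(rng.normal(size=n))
        y[0], y[1] = 1.0, -1.0  # both classes present
        C = float(rng.choice([0.1, 1.0, 10.0]))
        model = train_linear_svm(X, y, C=C)
        obj = svm_objective(model, X, y)
        _, _, obj_star = brute_force_svm(X, y, C)
        assert obj == pytest.approx(obj_star, rel=1e-4, abs=1e-8)

    def test_separable_toy_set_against_oracle(self):
        X = np.array([[2.0, 2.0], [3.0, 3.0], [2.0, 3.5], [3.5, 2.0],
                      [-2.0, -2.0], [-3.0, -3.0], [-2.0, -3.5], [-3.5, -2.0]])
        y = np.r_[np.ones(4), -np.ones(4)]
        model = train_linear_svm(X, y, C=100.0)
        w, b, obj_star = brute_force_svm(X, y, 100.0)
        assert svm_objective(model, X, y) == pytest.approx(obj_star, rel=1e-4)

    def test_duplicating_points_with_halved_C_preserves_model(self, rng):
        X = np.vstack([rng.normal(1, 1, (8, 3)), rng.normal(-1, 1, (8, 3))])
        y = np.r_[np.ones(8), -np.ones(8)]
        m1 = train_linear_svm(X, y, C=2.0)
        m2 = train_linear_svm(np.vstack([X, X]), np.r_[y, y], C=1.0)
        assert np.allclose(m1.w, m2.w, atol=1e-5)
        assert m1.b == pytest.approx(m2.b, abs=1e-5)

    def test_agrees_with_reference_solver(self, rng):
        from sklearn.svm import SVC

        X = np.vstack([rng.normal(0.7, 1, (30, 4)), rng.normal(-0.7, 1, (25, 4))])
        y = np.r_[np.ones(30), -np.ones(25)]
        model = train_linear_svm(X, y, C=1.0)
        ref = SVC(kernel="linear", C=1.0, tol=1e-8).fit(X, y)
        assert np.allclose(model.w, ref.coef_.ravel(), atol=1e-4)
        assert model.b == pytest.approx(float(ref.intercept_[0]), abs=1e-3)

    def test_invalid_inputs(self):
        X = np.ones((3, 2))
        with pytest.raises(ValueError, match="both classes"):
            train_linear_svm(X, np.ones(3))
        with pytest.raises(ValueError, match="C must be positive"):
            train_linear_svm(X, np.array([1.0, -1.0, 1.0]), C=0.0)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            train_linear_svm(X, np.array([1.0, -1.0, 1.0]))


class TestPredict:
    @pytest.mark.parametrize(
        "x,expected", [((3, 5), 1), ((-2, 9), -1), ((0, 0), 1)]
    )
    def test_sign_rule_with_positive_ties(self, x, expected):
        model = LinearModel(w=np.array([1.0, 0.0]), b=0.0, C=1.0)
        assert predict(model, np.array([x], dtype=float))[0] == expected

    def test_dimension_mismatch(self):
        model = LinearModel(w=np.array([1.0, 0.0]), b=0.0, C=1.0)
        with pytest.raises(ValueError, match="dimension mismatch"):
            predict(model, np.zeros((1, 3)))


class TestConfusion:
    def test_all_correct_and_all_flipped(self):
        y = np.array([1, 1, 1, -1, -1])
        cm = confusion(y, y)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (3, 0, 0, 2)
        cm = confusion(-y, y)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (0, 3, 2, 0)

    @given(st.lists(st.sampled_from([-1, 1]), min_size=1, max_size=50), st.integers(0, 10**6))
    @settings(deadline=None, max_examples=50)
    def test_cells_partition_the_samples(self, labels, seed):
        y = np.array(labels)
        pred = np.array(np.random.default_rng(seed).choice([-1, 1], size=len(y)))
        assert confusion(pred, y).n == len(y)

    def test_label_validation(self):
        with pytest.raises(ValueError, match="labels"):
            confusion(np.array([0, 1]), np.array([1, 1]))


def _metrics_reference(tp, fn, fp, tn):
    """Exact rational re-implementation of the five formulas."""
    sens = Fraction(tp, tp + fn) if tp + fn else Fraction(0)
    spec = Fraction(tn, tn + fp) if tn + fp else Fraction(0)
    acc = Fraction(tp + tn, tp + fn + fp + tn)
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = float(tp * tn - fp * fn) / float(den) ** 0.5 if den else 0.0
    return float(sens), float(spec), float(acc), mcc, float((sens + spec) / 2)


class TestMetrics:
    def test_perfect_and_chance_classifiers(self):
        m = metrics(ConfusionMatrix(25, 0, 0, 25))
        assert (m.mcc, m.bacc_pct, m.accuracy) == (1.0, 100.0, 1.0)
        m = metrics(ConfusionMatrix(25, 25, 25, 25))
        assert (m.mcc, m.bacc_pct) == (0.0, 50.0)

    def test_hand_computed_case(self):
        m = metrics(ConfusionMatrix(tp=20, fn=10, fp=5, tn=20))
        assert m.sensitivity == pytest.approx(20 / 30)
        assert m.specificity == pytest.approx(20 / 25)
        assert m.mcc == pytest.approx(350 / 750, abs=1e-10)
        assert m.bacc_pct == pytest.approx(73.3333, abs=1e-3)

    def test_matches_independent_implementation_on_random_matrices(self, rng):
        for _ in range(1000):
            tp, fn, fp, tn = (int(v) for v in rng.integers(0, 40, 4))
            if tp + fn + fp + tn == 0:
                continue
            m = metrics(ConfusionMatrix(tp, fn, fp, tn))
            ref = _metrics_reference(tp, fn, fp, tn)
            assert m.sensitivity == pytest.approx(ref[0], abs=1e-12)
            assert m.specificity == pytest.approx(ref[1], abs=1e-12)
            assert m.accuracy == pytest.approx(ref[2], abs=1e-12)
            assert m.mcc == pytest.approx(ref[3], abs=1e-12)
            assert m.bacc == pytest.approx(ref[4], abs=1e-12)
            assert -1.0 <= m.mcc <= 1.0
            assert m.bacc == pytest.approx((m.sensitivity + m.specificity) / 2)

    @given(st.integers(0, 100), st.integers(0, 100), st.integers(0, 100),
           st.integers(0, 100))
    @settings(deadline=None, max_examples=200)
    def test_mcc_and_bacc_invariant_under_class_swap(self, tp, fn, fp, tn):
        if tp + fn + fp + tn == 0:
            return
        m1 = metrics(ConfusionMatrix(tp, fn, fp, tn))
        m2 = metrics(ConfusionMatrix(tn, fp, fn, tp))  # swap TP<->TN, FP<->FN
        assert m1.mcc == pytest.approx(m2.mcc, abs=1e-12)
        assert m1.bacc == pytest.approx(m2.bacc, abs=1e-12)


class TestRepeatedKfold:
    def _data(self, rng, n_pos=30, n_neg=25, sep=3.0):
        X = np.vstack([rng.normal(sep, 1, (n_pos, 3)), rng.normal(-sep, 1, (n_neg, 3))])
        y = np.r_[np.ones(n_pos), -np.ones(n_neg)]
        return X, y

    def test_fold_count_and_partition_property(self, rng):
        X, y = self._data(rng)
        cfg = CVConfig(folds=5, repeats=20, seed=3)
        res = repeated_kfold(X, y, cfg)
        assert len(res.fold_metrics) == 100
        fold_ids = fold_assignments(y, cfg)
        assert fold_ids.shape == (20, 55)
        # every sample lands in exactly one test fold per repeat, folds balanced
        for r in range(20):
            counts = np.bincount(fold_ids[r], minlength=5)
            assert counts.sum() == 55
            assert counts.min() >= 55 // 5

    def test_fold_assignment_depends_only_on_seed_and_repeat(self):
        y = np.r_[np.ones(30), -np.ones(25)]
        a = fold_assignments(y, CVConfig(seed=9))
        b = fold_assignments(y, CVConfig(seed=9))
        c = fold_assignments(y, CVConfig(seed=10))
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_stratified_folds_contain_both_classes(self):
        y = np.r_[np.ones(30), -np.ones(25)]
        fold_ids = fold_assignments(y, CVConfig(seed=1))
        for r in range(20):
            for f in range(5):
                assert np.unique(y[fold_ids[r] == f]).size == 2

    def test_grouped_folding_keeps_subjects_together(self):
        y = np.r_[np.ones(30), -np.ones(30)]
        groups = np.repeat(np.arange(30), 2)  # two CIT rows per subject
        fold_ids = fold_assignments(y, CVConfig(seed=2, grouped=True), groups)
        for r in range(20):
            for g in np.unique(groups):
                assert np.unique(fold_ids[r][groups == g]).size == 1

    def test_separable_data_scores_perfectly(self, rng):
        X, y = self._data(rng, sep=5.0)
        res = repeated_kfold(X, y, CVConfig(repeats=3, seed=0), C=10.0)
        assert res.mean_mcc == pytest.approx(1.0)
        assert res.mean_bacc == pytest.approx(1.0)

    def test_too_few_samples_per_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        y = np.array([1.0, 1.0, 1.0, 1.0, -1.0, -1.0])
        with pytest.raises(ValueError, match="not enough samples"):
            repeated_kfold(X, y, CVConfig(folds=5, seed=0))


class TestCompareMetricDistributions:
    def test_identical_lists_give_zero_statistic(self):
        stat, p = compare_metric_distributions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stat == 0.0
        assert p == 1.0

    def test_constant_shift_detected_and_antisymmetric(self, rng):
        a = rng.normal(0, 1, 100)
        b = a + 10.0
        stat, p = compare_metric_distributions(b, a)
        assert stat > 0
        assert p < 1e-6
        stat2, p2 = compare_metric_distributions(a, b)
        assert stat2 == pytest.approx(-stat)
        assert p2 == pytest.approx(p)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            compare_metric_distributions([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(ValueError, match="at least two"):
            compare_metric_distributions([1.0], [1.0, 2.0])


class TestSerialization:
    def test_model_json_round_trip(self, tmp_path):
        model = LinearModel(w=np.array([0.5, -1.25]), b=0.75, C=2.0)
        path = tmp_path / "model.json"
        model.to_json(path, channels=("CH6", "CH13"), grouping="bilateral")
        back = LinearModel.from_json(path)
        assert np.allclose(back.w, model.w)
        assert back.b == model.b
        assert back.C == model.C

    def test_cv_results_csv_layout(self, tmp_path, rng):
        X = np.vstack([rng.normal(2, 1, (10, 2)), rng.normal(-2, 1, (10, 2))])
        y = np.r_[np.ones(10), -np.ones(10)]
        res = repeated_kfold(X, y, CVConfig(folds=5, repeats=2, seed=0))
        path = tmp_path / "cv.csv"
        res.to_csv(path, folds=5)
        import pandas as pd

        frame = pd.read_csv(path)
        assert len(frame) == 10
        assert list(frame.columns) == [
            "repeat", "fold", "TP", "FN", "FP", "TN",
            "sensitivity", "specificity", "accuracy", "MCC", "bACC",
        ]
        assert (frame[["TP", "FN", "FP", "TN"]].sum(axis=1) == 4).all()
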