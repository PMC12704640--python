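"""DESI ratio, threshold classification, ROC/AUC and evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from desimri.metrics import (ClassifierConfig, DesiThresholdClassifier,
                             best_threshold, classify_desi, compute_desi,
                             confusion_metrics, dice_3d, hausdorff_mm,
                             landmark_error_mm, roc_auc)
from desimri.volumetrics import VolumeReport


def _report(syl, sup):
    return VolumeReport(syl / 2, syl / 2, syl, sup * 1.5, sup, {}, 25.0)


class TestDesi:
    def test_ratio(self):
        r = compute_desi(_report(10.0, 5.0))
        assert r.desi == pytest.approx(2.0)
        assert r.defined

    def test_zero_numerator(self):
        assert compute_desi(_report(0.0, 5.0)).desi == 0.0

    def test_zero_denominator_flagged_not_infinite(self):
        r = compute_desi(_report(10.0, 0.0))
        assert not r.defined
        assert np.isnan(r.desi)

    def test_phantom_truth_desi_within_5pct(self, default_phantom):
        from desimri.volumetrics import compute_volume_report
        _, _, truth = default_phantom
        rep = compute_volume_report(truth.label_mask, truth.landmarks)
        r = compute_desi(rep)
        assert abs(r.desi / truth.analytic_desi - 1.0) < 0.05


class TestClassify:
    def test_published_thresholds(self):
        cfg = ClassifierConfig()
        assert cfg.desh_vs_nondesh_nph == 6.10
        assert cfg.desh_vs_other_groups == 4.83
        assert cfg.nph_vs_all == 1.92

    @pytest.mark.parametrize("desi,threshold,label", [
        (5.0, 4.83, "positive"),
        (4.83, 4.83, "positive"),   # tie rule: >= is positive
        (1.0, 6.10, "negative"),
    ])
    def test_threshold_rule(self, desi, threshold, label):
        assert classify_desi(desi, threshold) == label

    def test_undefined_desi_positive_with_warning(self):
        r = compute_desi(_report(10.0, 0.0))
        with pytest.warns(UserWarning, match="undefined"):
            out = classify_desi(r, 4.83)
        assert out.label == "positive"


class TestConfusionMetrics:
    def test_published_derivation(self):
        """46 DESH cases with 2 misses against 48 negatives, no false alarms."""
        m = confusion_metrics(tp=44, fn=2, tn=48, fp=0)
        assert round(100 * m.sensitivity, 1) == 95.7
        assert round(100 * m.accuracy, 1) == 97.9
        assert m.specificity == 1.0
        assert m.precision == 1.0

    def test_balanced_counts_give_half_accuracy(self):
        m = confusion_metrics(5, 5, 5, 5)
        assert m.accuracy == 0.5

    def test_perfect_classifier(self):
        m = confusion_metrics(7, 0, 9, 0)
        assert (m.sensitivity, m.specificity, m.precision, m.f1, m.accuracy) \
            == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(3, 1, 0, 0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(tp=st.integers(0, 50), fn=st.integers(0, 50),
           tn=st.integers(0, 50), fp=st.integers(0, 50))
    def test_identities_hold(self, tp, fn, tn, fp):
        if tp + fn == 0 or tn + fp == 0:
            return
        m = confusion_metrics(tp, fn, tn, fp)
        assert m.sensitivity == pytest.approx(tp / (tp + fn))
        assert m.specificity == pytest.approx(tn / (tn + fp))
        assert m.accuracy == pytest.approx((tp + tn) / (tp + fn + tn + fp))
        for v in (m.sensitivity, m.specificity, m.precision, m.f1, m.accuracy):
            assert 0.0 <= v <= 1.0
        if m.precision + m.sensitivity > 0:
            assert m.f1 == pytest.approx(
                2 * m.precision * m.sensitivity / (m.precision + m.sensitivity))


def _brute_force_auc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 9, 10], [0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert roc_auc([3, 3, 3, 3], [0, 1, 0, 1]) == 0.5

    def test_worked_pairwise_example(self):
        # pos {3, 2}, neg {1, 2}: pairwise (1 + 1 + 1 + 0.5)/4
        assert roc_auc([3, 2, 1, 2], [1, 1, 0, 0]) == pytest.approx(0.875)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])

    def test_matches_bruteforce_and_sklearn_on_random_cohorts(self, rng):
        for _ in range(100):
            n = rng.integers(4, 51)
            labels = np.zeros(n, int)
            labels[: rng.integers(1, n)] = 1
            rng.shuffle(labels)
            scores = np.round(rng.normal(size=n) + labels, 1)  # ties likely
            a = roc_auc(scores, labels)
            assert a == pytest.approx(_brute_force_auc(scores, labels), abs=1e-12)
            assert a == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestBestThreshold:
    def test_separable_midpoint(self):
        assert best_threshold([10, 9, 1, 2], [1, 1, 0, 0]) == pytest.approx(5.5)

    def test_degenerate_identical_scores(self):
        assert best_threshold([4, 4, 4], [1, 0, 1]) == 4.0

    def test_ties_break_to_smallest(self):
        # two thresholds reach J = 0.5; the smaller midpoint wins
        t = best_threshold([1, 2, 3, 4], [0, 1, 0, 1])
        assert t == pytest.approx(1.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            best_threshold([1, 2], [0, 0])


class TestThresholdClassifierEstimator:
    def test_fixed_threshold_predicts(self):
        clf = DesiThresholdClassifier(threshold=4.83).fit([[1.0], [9.0]], [0, 1])
        np.testing.assert_array_equal(clf.predict([[4.83], [4.82], [9.0]]),
                                      [1, 0, 1])

    def test_learned_threshold_separates(self):
        X = np.array([1.2, 1.5, 7.0, 8.0])[:, None]
        y = [0, 0, 1, 1]
        clf = DesiThresholdClassifier().fit(X, y)
        assert 1.5 < clf.threshold_ < 7.0
        assert clf.score(X, y) == 1.0

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone
        clf = DesiThresholdClassifier(threshold=2.0)
        assert clone(clf).get_params() == clf.get_params()


class TestDice3D:
    def test_identical(self, rng):
        a = rng.random((6, 6, 6)) > 0.5
        assert dice_3d(a, a) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0], b[2] = True, True
        assert dice_3d(a, b) == 0.0

    def test_nested_half_volume(self):
        b = np.zeros((4, 4, 4), bool)
        b[:2] = True  # |B| = 32
        a = np.zeros((4, 4, 4), bool)
        a[0] = True   # |A| = 16, A subset of B
        assert dice_3d(a, b) == pytest.approx(2 / 3)

    def test_both_empty_is_one(self):
        e = np.zeros((3, 3, 3), bool)
        assert dice_3d(e, e) == 1.0

    def test_symmetric(self, rng):
        a = rng.random((5, 5, 5)) > 0.5
        b = rng.random((5, 5, 5)) > 0.5
        assert dice_3d(a, b) == dice_3d(b, a)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_3d(np.zeros((2, 2, 2), bool), np.zeros((3, 3, 3), bool))


class TestHausdorff:
    def test_identical_zero(self):
        a = np.zeros((8, 8, 8), bool)
        a[2:5, 2:5, 2:5] = True
        assert hausdorff_mm(a, a) == 0.0

    def test_two_voxels_three_steps(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[1, 1, 1] = True
        b[4, 1, 1] = True
        assert hausdorff_mm(a, b, (1, 1, 1)) == pytest.approx(3.0)

    def test_translated_cube_with_anisotropic_spacing(self):
        a = np.zeros((12, 12, 12), bool)
        b = np.zeros((12, 12, 12), bool)
        a[2:6, 2:6, 2:6] = True
        b[4:8, 2:6, 2:6] = True  # shifted 2 voxels along x at 0.5 mm
        assert hausdorff_mm(a, b, (0.5, 1.0, 1.0)) == pytest.approx(1.0)

    def test_symmetric(self, rng):
        a = rng.random((7, 7, 7)) > 0.6
        b = rng.random((7, 7, 7)) > 0.6
        assert hausdorff_mm(a, b) == hausdorff_mm(b, a)

    def test_empty_rejected(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        b[1, 1, 1] = True
        with pytest.raises(ValueError):
            hausdorff_mm(a, b)


class TestLandmarkError:
    def test_zero_and_pythagoras(self):
        assert landmark_error_mm((1, 2, 3), (1, 2, 3)) == 0.0
        assert landmark_error_mm((0, 0, 0), (3, 4, 0)) == 5.0

    def test_batch_mean_is_mean_of_norms(self, rng):
        preds = rng.normal(size=(10, 3))
        truths = rng.normal(size=(10, 3))
        errs = [landmark_error_mm(p, t) for p, t in zip(preds, truths)]
        assert np.mean(errs) == pytest.approx(
            np.mean(np.linalg.norm(preds - truths, axis=1)))
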