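"""Splits, the two classifier backends, and confusion-matrix learning."""

import numpy as np
import pytest

from intentsense.classifiers import (
    CentroidClassifier,
    ConfusionMatrixSet,
    learn_confusion_matrices,
    make_splits,
    predict_window,
    train_sensor_classifier,
)
from intentsense.config import PipelineConfig
from intentsense.lstm import BiLSTMClassifier


class TestSplits:
    def test_study_sized_loso(self):
        ids = [f"S{i:02d}" for i in range(34)]
        splits = make_splits(ids, seed=0)
        assert len(splits) == 34
        for sp in splits:
            assert len(sp.training_subjects) == 33
            assert {len(sp.classifier_learning), len(sp.cm_learning)} == {17, 16}
            assert sp.test_subject not in sp.training_subjects
            assert set(sp.training_subjects) | {sp.test_subject} == set(ids)

    def test_each_subject_held_out_once(self):
        ids = list("ABCDE")
        splits = make_splits(ids, seed=1)
        assert sorted(sp.test_subject for sp in splits) == sorted(ids)

    def test_deterministic_under_seed(self):
        ids = list("ABCDEFG")
        assert make_splits(ids, seed=3) == make_splits(ids, seed=3)

    def test_too_small_cohort(self):
        with pytest.raises(ValueError):
            make_splits(["A", "B"], seed=0)


def _separable_windows(n_per_class=4, width=18, seed=0):
    rng = np.random.default_rng(seed)
    windows, labels = [], []
    for c in range(3):
        mean = np.zeros(width)
        mean[c] = 5.0
        for _ in range(n_per_class):
            windows.append(mean + 0.01 * rng.normal(size=(25, width)))
            labels.append(c)
    return np.stack(windows), np.array(labels)


class TestCentroidBackend:
    def test_own_window_classified_with_probability_one(self):
        x, y = _separable_windows(n_per_class=1)
        clf = train_sensor_classifier(x, y, "imu_ul", backend="lightweight")
        for i in range(3):
            probs, vote = predict_window(clf, x[i])
            assert vote == y[i]
            assert probs[y[i]] == 1.0

    def test_separable_fixture_trains_to_perfect_accuracy(self):
        x, y = _separable_windows()
        clf = train_sensor_classifier(x, y, "imu_ul", backend="lightweight")
        assert np.array_equal(clf.predict_votes(x), y)

    def test_probabilities_sum_to_one_and_tie_break(self):
        x, y = _separable_windows()
        clf = train_sensor_classifier(x, y, "imu_ul", backend="lightweight")
        probs, vote = predict_window(clf, np.zeros((25, 18)))
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        # equidistant from centroids 1 and 2 after zeroing those axes: the
        # argmax tie-break picks the lowest class index
        sym = np.zeros((25, 18))
        clf2 = CentroidClassifier("s", 2)
        clf2.centroids_ = np.array([[1.0, 0.0], [0.0, 1.0], [5.0, 5.0]])
        p, v = predict_window(clf2, np.zeros((25, 2)))
        assert v == 0  # classes 0 and 1 tie at equal distance

    def test_width_mismatch_rejected(self):
        x, y = _separable_windows()
        clf = train_sensor_classifier(x, y, "imu_ul", backend="lightweight")
        with pytest.raises(ValueError, match="width"):
            predict_window(clf, np.zeros((25, 12)))

    def test_missing_class_is_degenerate(self):
        x, y = _separable_windows()
        with pytest.raises(ValueError, match="degenerate"):
            train_sensor_classifier(x[y != 2], y[y != 2], "imu_ul")

    def test_string_labels_accepted(self):
        x, _ = _separable_windows(n_per_class=2)
        labels = ["door", "door", "cardigan", "cardigan", "toast", "toast"]
        clf = train_sensor_classifier(x, labels, "imu_ul")
        assert np.array_equal(clf.predict_votes(x), [0, 0, 1, 1, 2, 2])


class TestLSTMBackend:
    def test_gradients_match_finite_differences(self):
        net = BiLSTMClassifier(n_features=4, hidden_units=3, seed=0)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(3, 5, 4))
        y = np.array([0, 1, 2])
        loss0, grads = net._gradients(x, y)
        params = net._params()
        eps = 1e-6
        for p, g in zip(params, grads):
            idx = np.unravel_index(np.argmax(np.abs(g)), g.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp, _ = net._gradients(x, y)
            p[idx] = orig - eps
            lm, _ = net._gradients(x, y)
            p[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert numeric == pytest.approx(g[idx], rel=1e-4, abs=1e-8)

    def test_overfits_separable_windows(self):
        x, y = _separable_windows(n_per_class=5, width=6, seed=2)
        cfg = PipelineConfig(backend="lstm", epochs=40, hidden_units=8, batch_size=8)
        clf = train_sensor_classifier(x, y, "imu_ul", backend="lstm", config=cfg, seed=0)
        probs = clf.predict_proba(x)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.array_equal(np.argmax(probs, axis=1), y)
        assert clf.net.loss_history_[-1] < clf.net.loss_history_[0]

    def test_seeded_reproducibility(self):
        x, y = _separable_windows(n_per_class=3, width=5, seed=3)
        cfg = PipelineConfig(backend="lstm", epochs=3, hidden_units=4, batch_size=4)
        a = train_sensor_classifier(x, y, "s", backend="lstm", config=cfg, seed=7)
        b = train_sensor_classifier(x, y, "s", backend="lstm", config=cfg, seed=7)
        assert np.array_equal(a.predict_proba(x), b.predict_proba(x))


class TestConfusionMatrices:
    def test_perfect_classifier_smoothed_hand_count(self):
        """10 trials per class, all voted correctly, alpha=1 smoothing:
        diagonal likelihood is (10+1)/(10+3) = 11/13."""
        labels = np.repeat([0, 1, 2], 10)
        votes = {"imu_ul": labels[:, None].repeat(4, axis=1)}
        cms = learn_confusion_matrices(votes, labels, n_steps=4, smoothing_alpha=1.0)
        like = cms.likelihood("imu_ul", 1)
        assert np.allclose(np.diag(like), 11 / 13)
        assert np.allclose(like[0, 1], 1 / 13)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, size=60)
        votes = {"a": rng.integers(0, 3, size=(60, 5))}
        cms = learn_confusion_matrices(votes, labels, n_steps=5)
        assert np.allclose(cms.likelihoods("a").sum(axis=-1), 1.0, atol=1e-12)
        assert np.all(cms.likelihoods("a") > 0)

    def test_random_classifier_tends_to_uniform(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 3, size=3000)
        votes = {"a": rng.integers(0, 3, size=(3000, 1))}
        cms = learn_confusion_matrices(votes, labels, n_steps=1)
        assert np.allclose(cms.likelihood("a", 1), 1 / 3, atol=0.05)

    def test_zero_windows_warns_and_gives_pseudo_counts(self):
        with pytest.warns(UserWarning, match="pseudo-counts"):
            cms = learn_confusion_matrices(
                {"a": np.zeros((0, 2), dtype=int)}, np.zeros(0, dtype=int), n_steps=2
            )
        assert np.allclose(cms.likelihood("a", 1), 1 / 3)

    def test_pooled_likelihood_sums_counts_over_steps(self):
        labels = np.array([0, 1, 2, 0, 1, 2])
        votes = {"a": np.column_stack([labels, (labels + 1) % 3])}
        cms = learn_confusion_matrices(votes, labels, n_steps=2, smoothing_alpha=0.0)
        summed = cms.counts["a"].sum(axis=0)
        expected = summed / summed.sum(axis=-1, keepdims=True)
        assert np.allclose(cms.pooled_likelihood("a"), expected, atol=1e-12)

    def test_sensor_accuracy_is_terminal_mean_diagonal(self):
        labels = np.repeat([0, 1, 2], 4)
        votes = {"a": np.column_stack([np.zeros(12, dtype=int), labels])}
        cms = learn_confusion_matrices({"a": votes["a"]}, labels, n_steps=2)
        assert cms.sensor_accuracy("a") == pytest.approx(
            np.mean(np.diag(cms.likelihood("a", 2)))
        )
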