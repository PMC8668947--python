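"""Elementary network operations against oracles, plus classifier contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ramangan.classifiers import (
    ClassifierSpec,
    conv1d_map,
    cross_entropy,
    filterwise_max_pool,
    pca_project,
    pca_reduce,
    predict_proba,
    softmax_output,
    train_classifier,
)


class TestConv1d:
    def test_difference_filter(self):
        out = conv1d_map([1, 2, 3, 4, 5, 6], [-1, 0, 1], 0.0)
        assert np.array_equal(out, [2, 2, 2, 2])

    def test_rectifier_clips(self):
        out = conv1d_map([1, 2, 3, 4, 5, 6], [1, 0, -1], 0.0)
        assert np.array_equal(out, [0, 0, 0, 0])

    def test_output_length_reference_sizes(self):
        x = np.zeros(1608)
        assert conv1d_map(x, np.ones(5)).shape == (1604,)

    def test_kernel_too_wide(self):
        with pytest.raises(ValueError):
            conv1d_map([1, 2], [1, 2, 3])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_sliding_window_oracle(self, seed):
        """conv1d_map equals an explicit python-loop sliding dot product."""
        rng = np.random.default_rng(seed)
        d = int(rng.integers(2, 50))
        k = int(rng.integers(1, d + 1))
        x = rng.normal(0, 1, d)
        w = rng.normal(0, 1, k)
        b = float(rng.normal())
        expected = [max(0.0, float(np.dot(w, x[l:l + k]) + b)) for l in range(d - k + 1)]
        assert np.abs(conv1d_map(x, w, b) - expected).max() < 1e-9


class TestMaxPool:
    def test_filter_mode_pools_over_filters(self):
        F = np.array([[1.0, 3.0], [2.0, 0.0]])
        assert np.array_equal(filterwise_max_pool(F, "filter"), [2.0, 3.0])

    def test_single_filter_identity(self):
        F = np.array([[1.0, 5.0, 2.0]])
        assert np.array_equal(filterwise_max_pool(F, "filter"), F[0])

    def test_global_mode_pools_over_positions(self):
        F = np.array([[1.0, 3.0], [2.0, 0.0]])
        assert np.array_equal(filterwise_max_pool(F, "global"), [3.0, 2.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            filterwise_max_pool(np.empty((0, 0)))


class TestSoftmaxHead:
    def test_uniform_on_equal_logits(self):
        W = np.zeros((2, 3))
        out = softmax_output(np.array([1.0, 2.0]), W, np.zeros(3))
        assert np.allclose(out, 1 / 3)

    def test_shift_invariance(self):
        W = np.eye(3)
        b = np.zeros(3)
        p1 = softmax_output(np.array([1.0, 2.0, 0.5]), W, b)
        p2 = softmax_output(np.array([1.0, 2.0, 0.5]), W, b + 7.3)
        assert np.allclose(p1, p2, atol=1e-12)

    def test_dominant_logit(self):
        out = softmax_output(np.array([10.0, 0.0, 0.0]), np.eye(3), np.zeros(3))
        assert out[0] == pytest.approx(np.exp(10) / (np.exp(10) + 2))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            softmax_output(np.zeros(2), np.zeros((3, 3)), np.zeros(3))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        feats = rng.normal(0, 3, (4, 5))
        W = rng.normal(0, 1, (5, 3))
        b = rng.normal(0, 1, 3)
        out = softmax_output(feats, W, b)
        assert np.abs(out.sum(axis=1) - 1).max() < 1e-9
        assert np.all(out > 0)


class TestCrossEntropy:
    def test_perfect_predictions(self):
        y = np.eye(3)
        assert cross_entropy(y, y) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_predictions(self):
        y = np.eye(3)
        p = np.full((3, 3), 1 / 3)
        assert cross_entropy(y, p) == pytest.approx(np.log(3))

    def test_hand_arithmetic(self):
        y = np.array([[1, 0], [0, 1]], dtype=float)
        p = np.array([[0.5, 0.5], [0.75, 0.25]])
        assert cross_entropy(y, p) == pytest.approx((np.log(2) + np.log(4)) / 2)

    def test_mismatched_rows(self):
        with pytest.raises(ValueError):
            cross_entropy(np.eye(3), np.eye(2))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_closed_form_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, k = int(rng.integers(1, 8)), 3
        labels = rng.integers(0, k, n)
        y = np.eye(k)[labels]
        p = rng.dirichlet(np.ones(k), size=n)
        expected = -np.mean([np.log(max(p[i, labels[i]], 1e-12)) for i in range(n)])
        assert cross_entropy(y, p) == pytest.approx(expected, abs=1e-9)


class TestPca:
    def test_full_rank_reconstruction(self, toy_dataset):
        rank = np.linalg.matrix_rank(toy_dataset.X - toy_dataset.X.mean(axis=0))
        basis = pca_reduce(toy_dataset, rank)
        Z = pca_project(basis, toy_dataset)
        back = basis.inverse_transform(Z)
        assert np.abs(back - toy_dataset.X).max() < 1e-8

    def test_train_mean_projects_to_origin(self, toy_dataset):
        basis = pca_reduce(toy_dataset, 2)
        z = basis.transform(toy_dataset.X.mean(axis=0, keepdims=True))
        assert np.abs(z).max() < 1e-9

    def test_component_cap(self, toy_dataset):
        with pytest.raises(ValueError):
            pca_reduce(toy_dataset, toy_dataset.n + 1)


class TestClassifierContracts:
    def test_lr_separable(self, toy_dataset):
        spec = ClassifierSpec(kind="LR", epochs=200)
        model = train_classifier(spec, toy_dataset, seed=0)
        _, labels = predict_proba(model, toy_dataset)
        assert np.mean(labels == toy_dataset.labels) == 1.0

    def test_determinism(self, toy_dataset):
        spec = ClassifierSpec(kind="CNN", epochs=5, filters=8, kernel=3)
        p1, _ = predict_proba(train_classifier(spec, toy_dataset, seed=4), toy_dataset)
        p2, _ = predict_proba(train_classifier(spec, toy_dataset, seed=4), toy_dataset)
        assert np.array_equal(p1, p2)

    @pytest.mark.parametrize("kind", ["LR", "PCA_LR", "SVM", "PCA_SVM", "MLP", "LSTM", "CNN"])
    def test_all_families_fit_and_emit_probabilities(self, toy_dataset, kind):
        spec = ClassifierSpec(kind=kind, epochs=10, filters=6, kernel=3,
                              pca_components=3, lstm_window=4)
        model = train_classifier(spec, toy_dataset, seed=1)
        proba, labels = predict_proba(model, toy_dataset)
        assert proba.shape == (toy_dataset.n, 3)
        assert np.abs(proba.sum(axis=1) - 1).max() < 1e-6
        assert set(labels) <= set(toy_dataset.class_set)

    def test_tie_breaks_toward_lowest_class_index(self, toy_dataset):
        spec = ClassifierSpec(kind="LR", epochs=0)

        model = train_classifier(spec, toy_dataset, seed=0)
        proba = np.full((1, 3), 1 / 3)
        assert model.classes_[np.argmax(proba, axis=1)][0] == "BCC"

    def test_single_class_rejected(self, single_class_dataset):
        with pytest.raises(ValueError):
            train_classifier(ClassifierSpec(kind="LR", epochs=1), single_class_dataset)

    def test_axis_mismatch_rejected(self, toy_dataset, single_class_dataset):
        model = train_classifier(ClassifierSpec(kind="LR", epochs=1), toy_dataset, seed=0)
        other = single_class_dataset
        other = type(other)(
            axis=type(other.axis)(0.0, 1.0, other.d),
            X=other.X, labels=other.labels, treated=other.treated,
            sample_ids=other.sample_ids,
        )
        with pytest.raises(ValueError):
            predict_proba(model, other)

    def test_cnn_loss_nonincreasing_on_separable_data(self, toy_dataset):
        """Full-batch training loss decreases (<=5% transient violations)."""
        spec = ClassifierSpec(kind="CNN", epochs=60, filters=8, kernel=3,
                              batch_size=64)
        model = train_classifier(spec, toy_dataset, seed=0)
        hist = np.array(model.loss_history_)
        violations = np.sum(np.diff(hist) > 1e-9)
        assert violations <= 0.05 * len(hist)
        assert hist[-1] < hist[0]

    def test_cnn_global_pooling_mode(self, toy_dataset):
        spec = ClassifierSpec(kind="CNN", epochs=10, filters=6, kernel=3,
                              pooling="global")
        model = train_classifier(spec, toy_dataset, seed=0)
        proba, _ = predict_proba(model, toy_dataset)
        assert np.abs(proba.sum(axis=1) - 1).max() < 1e-6

    def test_cnn_trains_to_perfect_accuracy_on_separated_classes(self):
        from ramangan.synthetic import generate_benchmark, separable_benchmark_config

        ds = generate_benchmark(separable_benchmark_config(seed=0, per_class=10, d=96))
        spec = ClassifierSpec(kind="CNN", epochs=100, filters=16, kernel=5)
        model = train_classifier(spec, ds, seed=0)
        _, labels = predict_proba(model, ds)
        assert np.mean(labels == ds.labels) == 1.0
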