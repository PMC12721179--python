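"""One-against-one SVM decoding: structure, voting, metrics, calibration."""

import numpy as np
import pytest

from gaitcode.decoding import (
    DecoderSpec,
    TrialTensor,
    build_trials,
    error_metrics,
    evaluate,
    fit_ovo_svm,
    predict_vote,
    prepost_summary,
    shuffle_null,
    size_sweep,
)


def _gaussian_tensor(n_trials, n_units, n_classes, sep=3.0, seed=0, task="time"):
    """Separable synthetic tensor: class-specific unit means + noise."""
    rng = np.random.default_rng(seed)
    mu = rng.uniform(2, 10, size=(n_units, n_classes)) + sep * rng.standard_normal(
        (n_units, n_classes)
    )
    mu = np.abs(mu)
    data = np.abs(
        mu[None, :, :] + 0.5 * rng.standard_normal((n_trials, n_units, n_classes))
    )
    if task == "time":
        cvals = -1.5 + 0.2 * (np.arange(n_classes) + 0.5)
    elif task == "phase":
        cvals = (np.arange(n_classes) + 0.5) * 360.0 / n_classes
    else:
        cvals = 75.0 + 50.0 * np.arange(n_classes)
    return TrialTensor(task, data, cvals)


def _flat(tensor):
    t, u, k = tensor.data.shape
    X = np.transpose(tensor.data, (0, 2, 1)).reshape(t * k, u)
    y = np.tile(np.arange(k), t)
    return X, y


class TestOvoStructure:
    @pytest.mark.parametrize("k,expected", [(15, 105), (12, 66), (4, 6)])
    def test_classifier_count(self, k, expected):
        X, y = _flat(_gaussian_tensor(4, 5, k))
        model = fit_ovo_svm(X, y)
        assert len(model.classifiers) == expected

    def test_separable_training_accuracy(self):
        X, y = _flat(_gaussian_tensor(10, 8, 2, sep=8.0))
        model = fit_ovo_svm(X, y)
        assert np.mean(predict_vote(model, X) == y) == 1.0

    def test_undersized_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        y = np.array([0, 0, 1, 1, 2])
        with pytest.raises(ValueError, match="class 2"):
            fit_ovo_svm(X, y)

    def test_training_centroid_classified(self):
        tensor = _gaussian_tensor(20, 10, 6, sep=6.0)
        X, y = _flat(tensor)
        model = fit_ovo_svm(X, y)
        centroids = np.stack([X[y == k].mean(axis=0) for k in range(6)])
        assert np.array_equal(predict_vote(model, centroids), np.arange(6))

    def test_vote_deterministic(self):
        X, y = _flat(_gaussian_tensor(6, 4, 5, sep=0.0, seed=3))
        model = fit_ovo_svm(X, y)
        probe = np.zeros((7, 4))  # far from data: votes can tie
        a = predict_vote(model, probe)
        b = predict_vote(model, probe)
        assert np.array_equal(a, b)


class TestErrorMetrics:
    def test_perfect_prediction_zero(self):
        assert error_metrics(np.array([1.0, 2.0]), np.array([1.0, 2.0]), "time") == 0
        assert error_metrics(np.array([30.0]), np.array([30.0]), "phase") == 0

    def test_angular_wrap(self):
        assert error_metrics(np.array([350.0]), np.array([10.0]), "phase") == 20.0

    def test_uniform_phase_mae_is_90(self):
        centers = (np.arange(12) + 0.5) * 30.0
        a, p = np.meshgrid(centers, centers)
        assert error_metrics(a.ravel(), p.ravel(), "phase") == pytest.approx(90.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            error_metrics(np.array([1.0]), np.array([1.0, 2.0]), "time")


@pytest.fixture(scope="module")
def informative_result():
    tensor = _gaussian_tensor(12, 30, 15, sep=2.0, seed=4)
    spec = DecoderSpec(
        n_units=20, n_draws=3, n_eval_iterations=8, tune=False, seed=9
    )
    return evaluate(tensor, spec)


class TestEvaluate:

    def test_confusion_rows_sum_to_one(self, informative_result):
        assert np.allclose(informative_result.confusion.sum(axis=1), 1.0)

    def test_above_chance_on_separable_data(self, informative_result):
        assert informative_result.overall_accuracy > 3 / 15

    def test_deterministic_under_seed(self):
        tensor = _gaussian_tensor(8, 10, 4, seed=5, task="speed")
        spec = DecoderSpec(n_units=8, n_draws=2, n_eval_iterations=4, tune=False, seed=3)
        a = evaluate(tensor, spec)
        b = evaluate(tensor, spec)
        assert np.array_equal(a.confusion, b.confusion)
        assert a.overall_accuracy == b.overall_accuracy
        assert np.array_equal(a.per_draw_accuracy, b.per_draw_accuracy)

    def test_insufficient_trials_rejected(self):
        tensor = _gaussian_tensor(2, 5, 4, task="speed")
        with pytest.raises(ValueError, match="trials"):
            evaluate(tensor, DecoderSpec(n_holdout=2))


class TestPrePost:
    def test_flat_accuracy(self):
        res_cls = np.full(15, 0.1)
        from gaitcode.decoding import DecodingResult

        res = DecodingResult(
            task="time",
            confusion=np.eye(15),
            per_class_accuracy=res_cls,
            overall_accuracy=0.1,
            error_metric=0.0,
            error_metric_bins=0.0,
            per_draw_accuracy=np.array([0.1]),
            per_draw_per_class=res_cls[None, :],
            class_values=-1.5 + 0.2 * (np.arange(15) + 0.5),
            n_units=10,
        )
        pp = prepost_summary(res)
        assert pp["pre"] == pytest.approx(0.1)
        assert pp["post"] == pytest.approx(0.1)
        assert pp["pre_bins"] == 3 and pp["post_bins"] == 3

    def test_non_time_task_rejected(self):
        tensor = _gaussian_tensor(8, 10, 12, task="phase")
        spec = DecoderSpec(n_units=8, n_draws=1, n_eval_iterations=2, tune=False)
        res = evaluate(tensor, spec)
        with pytest.raises(ValueError, match="time"):
            prepost_summary(res)


class TestSizeSweep:
    def test_single_point_on_small_cohort(self):
        tensor = _gaussian_tensor(8, 10, 4, task="speed")
        spec = DecoderSpec(n_draws=2, n_eval_iterations=3, tune=False, seed=1)
        out = size_sweep(tensor, spec, sizes=[10])
        assert len(out) == 1 and out[0]["n_units"] == 10

    def test_oversized_requests_truncated(self):
        tensor = _gaussian_tensor(8, 10, 4, task="speed")
        spec = DecoderSpec(n_draws=1, n_eval_iterations=2, tune=False, seed=1)
        with pytest.warns(UserWarning, match="truncated"):
            out = size_sweep(tensor, spec, sizes=[5, 10, 50])
        assert [o["n_units"] for o in out] == [5, 10]


@pytest.fixture(scope="module")
def segmented_cohort():
    from gaitcode.kinematics import segment_session
    from gaitcode.synth import CohortSpec, M1_LIKE, generate_cohort

    spec = CohortSpec(
        regions={"M1": M1_LIKE}, n_units=8, n_sessions=1,
        session_duration=240.0, seed=31,
    )
    cohort = generate_cohort(spec)
    return [segment_session(s) for s in cohort.sessions]


class TestBuildTrials:

    def test_time_tensor_shape(self, segmented_cohort):
        spec = DecoderSpec(trials_per_session=10, seed=2)
        tensor = build_trials(segmented_cohort, "time", spec)
        assert tensor.data.shape == (10, 8, 15)
        assert np.allclose(np.diff(tensor.class_values), 0.2)

    def test_phase_tensor_shape(self, segmented_cohort):
        spec = DecoderSpec(trials_per_session=30, seed=2)
        tensor = build_trials(segmented_cohort, "phase", spec)
        assert tensor.data.shape == (30, 8, 12)
        assert tensor.class_values[0] == 15.0

    def test_speed_class_edges(self, segmented_cohort):
        spec = DecoderSpec(trials_per_session=5, seed=2)
        tensor = build_trials(segmented_cohort, "speed", spec)
        assert tensor.data.shape[2] == 4
        # a 120 mm/s trial belongs to the second class (100-150)
        assert np.searchsorted([50, 100, 150, 200, 250], 120.0) - 1 == 1
        assert list(tensor.class_values) == [75.0, 125.0, 175.0, 225.0]

    def test_unmeetable_quota_excludes_session(self, segmented_cohort):
        spec = DecoderSpec(trials_per_session=10_000, seed=2)
        with pytest.warns(UserWarning, match="quota"):
            with pytest.raises(ValueError, match="quota"):
                build_trials(segmented_cohort, "time", spec)


class TestShuffleNull:
    def test_label_shuffle_centers_at_chance(self):
        tensor = _gaussian_tensor(10, 12, 4, sep=4.0, seed=8, task="speed")
        spec = DecoderSpec(
            n_units=10, n_draws=1, n_eval_iterations=4, tune=False, seed=11
        )
        band = shuffle_null(tensor, spec, n_shuffles=12)
        assert 0.5 / 4 < band["center"] < 2.0 / 4
        assert band["overall_band"][0] <= band["center"] <= band["overall_band"][1]

    def test_shuffled_labels_not_decodable(self):
        rng = np.random.default_rng(12)
        tensor = _gaussian_tensor(10, 12, 4, sep=4.0, seed=8, task="speed")
        shuffled = tensor.data.copy()
        for t in range(shuffled.shape[0]):
            shuffled[t] = shuffled[t][:, rng.permutation(4)]
        spec = DecoderSpec(
            n_units=10, n_draws=2, n_eval_iterations=6, tune=False, seed=13
        )
        res = evaluate(TrialTensor("speed", shuffled, tensor.class_values), spec)
        band = shuffle_null(tensor, spec, n_shuffles=15)
        assert band["overall_band"][0] - 0.05 <= res.overall_accuracy
        assert res.overall_accuracy <= band["overall_band"][1] + 0.05
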