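import numpy as np
import pytest

from flysummit import (
    CLASSES,
    build_features,
    evaluate,
    label_frames,
    sample_training_set,
    train,
)
from flysummit.classify import (
    N_FEATURES,
    TrainingSet,
    build_features_batch,
    lookback_times,
)
from flysummit.core import Cohort, DataError, FlyRecord

from conftest import make_trajectory


class TestBuildFeatures:
    def test_vector_length(self, small_cohort):
        traj = small_cohort.trajectories[0]
        for t_obs in (700.0, 3600.0, traj.t[-1]):
            assert build_features(traj, t_obs).shape == (N_FEATURES,)

    def test_constant_trajectory_values(self):
        # y = 0.5, speed = 0 everywhere, observed 2 h in
        traj = make_trajectory(n=3 * 3600 * 3, y_rel=0.5)
        v = build_features(traj, 7200.0)
        assert v[0] == pytest.approx(2.0)
        np.testing.assert_allclose(v[1:11], 0.5)
        np.testing.assert_allclose(v[11:21], 0.0)
        np.testing.assert_allclose(v[21:41], 0.5)
        np.testing.assert_allclose(v[41:61], 0.0)

    def test_lookbacks_are_geometric(self):
        # independent oracle: 10 * 10**(i/9) minutes for t_obs = 100 min
        times = lookback_times(6000.0, 0.0)
        lags_min = (6000.0 - times) / 60.0
        expected = 10 * 10 ** (np.arange(9, -1, -1) / 9)
        np.testing.assert_allclose(lags_min, expected, rtol=1e-12)
        # strictly decreasing lag toward the observation; extremes exact
        assert np.all(np.diff(lags_min) < 0)
        assert lags_min[0] == pytest.approx(100.0) and lags_min[-1] == pytest.approx(10.0)

    def test_too_early_observation_rejected(self, small_cohort):
        with pytest.raises(DataError):
            build_features(small_cohort.trajectories[0], 300.0)

    def test_causality(self, small_cohort):
        # changing frames after t_obs never changes the vector
        traj = small_cohort.trajectories[0]
        t_obs = 5000.0
        before = build_features(traj, t_obs)
        tampered = traj.copy()
        cut = np.searchsorted(traj.t, t_obs) + 1
        tampered.speed[cut:] = 99.0
        tampered.y_rel[cut:] = 0.99
        np.testing.assert_array_equal(build_features(tampered, t_obs), before)


class TestLabels:
    def test_survivor_all_never(self, small_cohort):
        for traj, rec in small_cohort:
            if rec.fly_class == "survivor":
                labels = label_frames(traj, rec)
                assert set(labels) == {"never"}

    def test_zombie_partition_counts(self):
        n, onset, death = 1000, 300, 700
        traj = make_trajectory(n=n)
        rec = FlyRecord("z", survival=0, outcome=1, death_frame=death,
                        death_source="manual")
        labels = label_frames(traj, rec, summit_onset=onset)
        counts = {c: int(np.sum(labels == c)) for c in CLASSES}
        assert (counts["pre"], counts["during"], counts["post"]) == (onset, death - onset, n - death)
        assert counts["never"] == 0
        assert sum(counts.values()) == n  # every frame exactly one label

    def test_onset_after_death_rejected(self):
        traj = make_trajectory(n=100)
        rec = FlyRecord("z", survival=0, outcome=1, death_frame=50, death_source="manual")
        with pytest.raises(DataError):
            label_frames(traj, rec, summit_onset=60)


class TestSampling:
    def test_total_example_count(self, small_cohort):
        ts = sample_training_set(small_cohort, n_per_fly=20,
                                 rng=np.random.default_rng(0))
        assert len(ts) == 20 * len(small_cohort)

    def test_zero_per_fly_empty(self, small_cohort):
        ts = sample_training_set(small_cohort, n_per_fly=0,
                                 rng=np.random.default_rng(0))
        assert len(ts) == 0

    def test_deterministic_under_seed(self, small_cohort):
        a = sample_training_set(small_cohort, 10, rng=np.random.default_rng(5))
        b = sample_training_set(small_cohort, 10, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_observation_times_respect_warmup(self, small_cohort):
        ts = sample_training_set(small_cohort, 50, rng=np.random.default_rng(1))
        assert np.all(ts.t_obs >= 600.0)


def _separable_set(n=400, seed=0):
    """Toy examples where 'during' has all speed features 1, others 0."""
    rng = np.random.default_rng(seed)
    X = np.zeros((n, N_FEATURES))
    labels = np.where(rng.random(n) < 0.5, "during", "never").astype(object)
    X[labels == "during", 11:21] = 1.0
    X[labels == "during", 41:61] = 1.0
    X[:, 0] = rng.uniform(0, 20, n)
    fly_ids = np.array([f"f{i % 20}" for i in range(n)], dtype=object)
    return TrainingSet(X, labels, fly_ids, np.arange(n, dtype=float))


class TestTrainEvaluate:
    def test_separable_toy_is_perfect(self):
        ts = _separable_set()
        model, report = train(ts, rng=np.random.default_rng(1), n_trees=30)
        for cls in ("during", "never"):
            assert report.precision[cls] == 1.0
            assert report.recall[cls] == 1.0
        # evaluating on the training data is perfect too
        rep2 = evaluate(model, ts.X, ts.labels)
        assert all(v == 1.0 for v in rep2.recall.values())

    def test_shuffled_labels_give_chance_precision(self):
        # permutation-null oracle: destroying the feature-label link leaves
        # per-class precision near class prevalence
        ts = _separable_set(n=2000, seed=2)
        rng = np.random.default_rng(3)
        ts.labels = rng.permutation(ts.labels)
        prevalence = np.mean(ts.labels == "during")
        model, report = train(ts, rng=np.random.default_rng(4), n_trees=50)
        assert report.precision["during"] == pytest.approx(prevalence, abs=0.12)

    def test_single_class_rejected(self):
        ts = _separable_set()
        ts.labels = np.full(len(ts), "never", dtype=object)
        with pytest.raises(DataError):
            train(ts, rng=np.random.default_rng(0))

    def test_empty_evaluation_rejected(self):
        ts = _separable_set()
        model, _ = train(ts, rng=np.random.default_rng(0), n_trees=10)
        with pytest.raises(DataError):
            evaluate(model, np.empty((0, N_FEATURES)), [])

    def test_confusion_rows_sum_to_supports(self):
        ts = _separable_set()
        model, _ = train(ts, rng=np.random.default_rng(0), n_trees=10)
        rep = evaluate(model, ts.X, ts.labels)
        for i, cls in enumerate(CLASSES):
            assert rep.confusion[i].sum() == int(np.sum(ts.labels == cls))


class TestEndToEnd:
    def test_classifier_beats_permutation_null(self, medium_cohort):
        # held-out recall for {never, during} must clear the label-shuffle
        # baseline by a wide margin on generator data
        rng = np.random.default_rng(9)
        ts = sample_training_set(medium_cohort, n_per_fly=150, rng=rng)
        model, report = train(ts, rng=np.random.default_rng(10), n_trees=100)
        # permutation-null baseline: with labels shuffled, expected recall of
        # a class equals its prevalence among predictions ~= its prevalence
        for cls in ("never", "during"):
            prevalence = float(np.mean(ts.labels == cls))
            assert report.recall[cls] >= prevalence + 0.3

    def test_influential_features_are_time_and_history(self, medium_cohort):
        # time of observation plus historical/current y and speed carry the
        # signal; check the time feature and behavioral history dominate
        ts = sample_training_set(medium_cohort, n_per_fly=150,
                                 rng=np.random.default_rng(13))
        _, report = train(ts, rng=np.random.default_rng(14), n_trees=100)
        imp = report.feature_importances
        order = np.argsort(imp)[::-1]
        assert 0 in set(order[:4])  # observation time
        assert set(order[:8]) & set(range(1, 11))  # historical y position
        # speed features carry real (if smaller) signal: best one in the
        # upper half of the ranking and a non-trivial importance share
        speed_feats = list(set(range(11, 21)) | set(range(41, 61)))
        assert set(order[:30]) & set(speed_feats)
        assert imp[speed_feats].sum() > 0.05
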