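"""Linear SVM training, score normalization and LOEO cross-validation."""

import numpy as np
import pytest

import erythroflow as ef
from erythroflow.classify import softmax_scores
from erythroflow.features import FeatureTable


def _table(matrix, video_ids=None):
    matrix = np.asarray(matrix, dtype=float)
    return FeatureTable(matrix=matrix,
                        roi_index=[f"r{i}" for i in range(len(matrix))],
                        backend_name="toy", video_ids=video_ids)


def _blobs(centers, n_per, spread, seed=0):
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for label, center in enumerate(centers):
        xs.append(rng.normal(center, spread, size=(n_per, len(center))))
        ys.append(np.full(n_per, label))
    return np.vstack(xs), np.concatenate(ys)


class TestTrainPredict:
    def test_separable_blobs_reach_perfect_training_accuracy(self):
        x, y = _blobs([(-5, 0), (5, 0)], 40, 0.3)
        model = ef.train(_table(x), y, "two_class")
        preds = ef.predict(model, _table(x))
        assert all(p.label == t for p, t in zip(preds, y))

    def test_four_corner_blobs_one_vs_all_separators(self):
        x, y = _blobs([(-5, -5), (5, -5), (-5, 5), (5, 5)], 30, 0.3)
        model = ef.train(_table(x), y, "four_class")
        assert model.svm.coef_.shape[0] == 4  # one separator per class
        preds = ef.predict(model, _table(x))
        assert np.mean([p.label == t for p, t in zip(preds, y)]) == 1.0

    def test_point_deep_inside_a_class_concentrates_scores(self):
        x, y = _blobs([(-5, -5), (5, -5), (-5, 5), (5, 5)], 30, 0.3)
        model = ef.train(_table(x), y, "four_class")
        p = ef.predict(model, _table([(-20, 30)]))[0]  # far into class 2
        assert p.label == 2
        assert p.scores[2] > 0.9

    def test_single_class_training_rejected(self):
        x, _ = _blobs([(0, 0)], 20, 1.0)
        with pytest.raises(ef.TrainingError):
            ef.train(_table(x), np.zeros(20, int), "two_class")

    def test_dimension_mismatch_rejected(self):
        x, y = _blobs([(-5, 0), (5, 0)], 10, 0.3)
        model = ef.train(_table(x), y, "two_class")
        with pytest.raises(ValueError):
            ef.predict(model, _table(np.zeros((3, 5))))


class TestScores:
    def test_boundary_point_splits_evenly_and_tiebreaks_low(self):
        scores = softmax_scores(np.array([0.0]), 2)
        assert scores[0] == pytest.approx((0.5, 0.5))
        assert int(np.argmax(scores[0])) == 0  # tie -> lowest class index

    def test_scores_sum_to_one_and_preserve_decision_ranking(self):
        rng = np.random.default_rng(7)
        decision = rng.normal(size=(50, 4)) * 3
        scores = softmax_scores(decision, 4)
        assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-9)
        assert (scores >= 0).all()
        for d_row, s_row in zip(decision, scores):
            assert np.array_equal(np.argsort(d_row), np.argsort(s_row))

    def test_permuted_labels_score_near_chance(self):
        """Destroying the labels leaves only the leave-group-out imbalance,
        which balanced class weights neutralize: accuracy ~= 50%."""
        rng = np.random.default_rng(3)
        n_videos, per = 20, 30
        x = rng.normal(size=(n_videos * per, 8))
        vids = [f"v{i:02d}" for i in range(n_videos) for _ in range(per)]
        labels = {f"v{i:02d}": int(l)
                  for i, l in enumerate(rng.permutation([0] * 10 + [1] * 10))}
        res = ef.run_loeo(_table(x, vids), labels, "two_class",
                          class_weight="balanced")
        assert abs(res.per_roi_accuracy(labels) - 0.5) < 0.1


class TestLoeo:
    def _grouped_table(self, n_videos=6, per=20, spread=0.3, seed=1):
        rng = np.random.default_rng(seed)
        labels = {f"v{i}": i % 2 for i in range(n_videos)}
        rows, vids = [], []
        for v, lab in labels.items():
            center = (-4, 0) if lab == 0 else (4, 0)
            rows.append(rng.normal(center, spread, size=(per, 2)))
            vids += [v] * per
        return _table(np.vstack(rows), vids), labels

    def test_two_videos_two_folds_swapped_training(self):
        table, labels = self._grouped_table(n_videos=2)
        res = ef.run_loeo(table, labels, "two_class")
        assert len(res.manifest) == 2
        assert res.manifest["n_train"].tolist() == [20, 20]
        assert res.manifest["n_test"].tolist() == [20, 20]

    def test_no_roi_in_both_partitions_of_a_fold(self):
        table, labels = self._grouped_table()
        res = ef.run_loeo(table, labels, "two_class")
        # per fold, train + test counts partition the cohort
        assert (res.manifest["n_train"] + res.manifest["n_test"]
                == table.n_rois).all()
        # predictions come exclusively from the held-out video per fold
        for video, n in res.manifest.set_index("video_id")["n_test"].items():
            assert sum(p.video_id == video for p in res.predictions) == n

    def test_separable_grouped_data_classified_correctly(self):
        table, labels = self._grouped_table()
        res = ef.run_loeo(table, labels, "two_class")
        assert res.per_roi_accuracy(labels) == 1.0
        assert "LOEO" in res.summary(labels)

    def test_single_class_training_fold_skipped_with_warning(self, caplog):
        # two videos share one class; the third holds all of class 1, so its
        # fold would train on class 0 only and must be skipped
        table, _ = self._grouped_table(n_videos=3)
        labels = {"v0": 0, "v1": 0, "v2": 1}
        with caplog.at_level("WARNING"):
            res = ef.run_loeo(table, labels, "two_class")
        row = res.manifest.set_index("video_id").loc["v2"]
        assert bool(row["skipped"])
        assert "single-class" in caplog.text
        # the other folds trained with both classes present
        others = res.manifest[res.manifest["video_id"] != "v2"]
        assert all("0,1" == c for c in others["train_classes"])

    def test_mean_training_rows_matches_fold_arithmetic(self):
        table, labels = self._grouped_table(n_videos=5, per=7)
        res = ef.run_loeo(table, labels, "two_class")
        n = table.n_rois
        expected = np.mean([n - 7] * 5)
        assert res.mean_training_rows == pytest.approx(expected)

    def test_fewer_than_two_videos_rejected(self):
        table, _ = self._grouped_table(n_videos=2)
        with pytest.raises(ef.TrainingError):
            ef.run_loeo(table, {"v0": 0, "v1": 1}, "two_class",
                        roi_video_ids=["v0"] * table.n_rois)
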