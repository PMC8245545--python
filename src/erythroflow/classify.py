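"""Linear SVM classification of ROI descriptors, with grouped cross-validation.

Two problems are supported: ``two_class`` (healthy 0 vs unhealthy 1) and
``four_class`` (healthy 0, SCD 1, THAL 2, HS 3, trained one-vs-all).  Each
ROI inherits the label of its source video: not every cell of a patient is
abnormal, so per-ROI labels are intentionally noisy and the video-level
cooperative decision rules (see :mod:`erythroflow.decision`) absorb that
noise.

Evaluation uses leave-one-experiment-out (LOEO) cross-validation: every fold
holds out all ROIs of exactly one video and trains on the rest, so no
within-video appearance correlation can leak into the test partition.  Any
per-fold feature selection is refitted on the training rows of that fold
only.  Decision values are mapped to normalized per-class scores with a
softmax, so every prediction carries a score vector summing to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .errors import TrainingError
from .features import FeatureTable
from .selection import SelectionMask, apply_mask, fit_low_variance_mask

logger = logging.getLogger(__name__)

PROBLEM_CLASSES = {"two_class": [0, 1], "four_class": [0, 1, 2, 3]}


@dataclass
class ScoredPrediction:
    """Per-ROI predicted label plus normalized per-class scores."""

    roi_id: str
    video_id: str
    label: int
    scores: np.ndarray   # one entry per class, in [0,1], summing to 1


@dataclass
class ClassifierModel:
    """A fitted linear SVM (one-vs-all for the four-class problem)."""

    problem: str
    class_labels: list[int]
    scaler: StandardScaler
    svm: LinearSVC
    mask: SelectionMask | None = None
    score_calibration: str = "softmax"


def softmax_scores(decision: np.ndarray, n_classes: int) -> np.ndarray:
    """Map SVM decision values to normalized per-class scores.

    Binary decision values ``d`` become the two-column matrix
    ``[-d/2, +d/2]`` before the row softmax, so a point exactly on the
    boundary scores (0.5, 0.5).  The softmax is monotone in the decision
    values, hence per-ROI score ranking equals decision-value ranking.
    """
    decision = np.asarray(decision, dtype=float)
    if decision.ndim == 1:
        decision = np.column_stack([-decision / 2.0, decision / 2.0])
    if decision.shape[1] != n_classes:
        raise ValueError("decision matrix width does not match class count")
    z = decision - decision.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def train(features: FeatureTable, labels: np.ndarray, problem: str,
          regularization: float = 1.0, class_weight=None,
          seed: int = 0) -> ClassifierModel:
    """Fit a linear SVM on (optionally pre-masked) features.

    Features are standardized (zero mean, unit variance on the training
    rows) before the hinge-loss fit; raw descriptor scales differ by orders
    of magnitude and a linear SVM is scale-sensitive.  Multiclass problems
    use the one-vs-all decomposition native to :class:`LinearSVC`.
    """
    if problem not in PROBLEM_CLASSES:
        raise ValueError(f"problem must be one of {sorted(PROBLEM_CLASSES)}")
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != features.n_rois:
        raise ValueError("labels must align with feature rows")
    present = np.unique(labels)
    if present.size < 2:
        raise TrainingError(
            f"training set contains a single class ({present.tolist()}); "
            "at least two classes are required")
    scaler = StandardScaler().fit(features.matrix)
    svm = LinearSVC(C=regularization, dual=False, max_iter=10000,
                    tol=1e-5, class_weight=class_weight, random_state=seed)
    svm.fit(scaler.transform(features.matrix), labels)
    return ClassifierModel(
        problem=problem,
        class_labels=list(PROBLEM_CLASSES[problem]),
        scaler=scaler,
        svm=svm,
    )


def predict(model: ClassifierModel, features: FeatureTable) -> list[ScoredPrediction]:
    """Score every row; label = argmax score (ties to the lowest class index)."""
    x = features.matrix
    if model.mask is not None:
        x = x[:, model.mask.retained]
    if x.shape[1] != model.scaler.n_features_in_:
        raise ValueError(
            f"feature dimensionality {x.shape[1]} does not match the model "
            f"({model.scaler.n_features_in_})")
    decision = np.asarray(
        model.svm.decision_function(model.scaler.transform(x)), dtype=float)
    n_classes = len(model.class_labels)
    svm_classes = [int(c) for c in model.svm.classes_]
    if decision.ndim == 1:  # binary SVM: one signed margin
        decision = np.column_stack([-decision / 2.0, decision / 2.0])
    if decision.shape[1] < n_classes:
        # classes absent from training get very negative decision values
        padded = np.full((decision.shape[0], n_classes), -1e6)
        for j, cls in enumerate(svm_classes):
            padded[:, model.class_labels.index(cls)] = decision[:, j]
        decision = padded
    scores = softmax_scores(decision, n_classes)
    video_ids = features.video_ids or [""] * features.n_rois
    out = []
    for i, roi_id in enumerate(features.roi_index):
        label = model.class_labels[int(np.argmax(scores[i]))]
        out.append(ScoredPrediction(roi_id=roi_id, video_id=video_ids[i],
                                    label=label, scores=scores[i]))
    return out


@dataclass
class LoeoResult:
    """Predictions and bookkeeping of one LOEO cross-validation run."""

    problem: str
    class_labels: list[int]
    predictions: list[ScoredPrediction]
    manifest: pd.DataFrame

    @property
    def mean_training_rows(self) -> float:
        done = self.manifest[~self.manifest["skipped"]]
        return float(done["n_train"].mean())

    def predictions_frame(self) -> pd.DataFrame:
        recs = [{
            "roi_id": p.roi_id, "video_id": p.video_id, "label": p.label,
            **{f"score_{c}": p.scores[j] for j, c in enumerate(self.class_labels)},
        } for p in self.predictions]
        return pd.DataFrame(recs)

    def per_roi_accuracy(self, video_labels: dict[str, int]) -> float:
        truth = np.array([video_labels[p.video_id] for p in self.predictions])
        pred = np.array([p.label for p in self.predictions])
        return float((truth == pred).mean())

    def summary(self, video_labels: dict[str, int] | None = None) -> str:
        lines = [
            f"LOEO cross-validation ({self.problem})",
            f"  folds:               {len(self.manifest)}"
            f" ({int(self.manifest['skipped'].sum())} skipped)",
            f"  total ROIs:          {int(self.manifest['n_test'].sum())}",
            f"  mean training ROIs:  {self.mean_training_rows:.0f}",
        ]
        if video_labels is not None:
            lines.append(
                f"  per-ROI accuracy:    {self.per_roi_accuracy(video_labels):.3f}")
        return "\n".join(lines)


def run_loeo(features: FeatureTable, video_labels: dict[str, int],
             problem: str, roi_video_ids: list[str] | None = None,
             selection: dict | None = None, regularization: float = 1.0,
             class_weight=None, seed: int = 0) -> LoeoResult:
    """Leave-one-experiment-out evaluation over videos.

    Parameters
    ----------
    features
        Full (unselected) feature table for every ROI of the cohort.
    video_labels
        Map video_id -> class label; ROIs inherit their video's label.
    roi_video_ids
        Grouping vector; defaults to ``features.video_ids``.
    selection
        Optional ``{"mode": ..., "value": ...}`` low-variance filter refitted
        inside every fold on the training rows only (leakage-safe).

    Returns
    -------
    LoeoResult
        Predictions concatenated over folds (fold order = sorted video ids)
        and a manifest with one row per fold: training/test row counts,
        classes present in training, retained feature columns.  A fold whose
        training partition is single-class is skipped with a warning and
        recorded as such.
    """
    groups = np.asarray(roi_video_ids if roi_video_ids is not None
                        else features.video_ids)
    if groups.shape[0] != features.n_rois:
        raise ValueError("every ROI needs a video id")
    unique_videos = sorted(set(groups))
    if len(unique_videos) < 2:
        raise TrainingError("LOEO needs at least 2 videos")
    labels = np.array([video_labels[v] for v in groups], dtype=int)

    predictions: list[ScoredPrediction] = []
    manifest_rows = []
    for video in unique_videos:
        test_idx = np.flatnonzero(groups == video)
        train_idx = np.flatnonzero(groups != video)
        train_classes = np.unique(labels[train_idx])
        row = {
            "video_id": video,
            "n_train": int(train_idx.size),
            "n_test": int(test_idx.size),
            "train_classes": ",".join(map(str, train_classes.tolist())),
            "skipped": False,
            "n_retained": None,
            "retained_idx": None,
        }
        if train_classes.size < 2:
            logger.warning("fold %s skipped: single-class training set", video)
            row["skipped"] = True
            manifest_rows.append(row)
            continue

        train_table = FeatureTable(
            matrix=features.matrix[train_idx],
            roi_index=[features.roi_index[i] for i in train_idx],
            backend_name=features.backend_name,
            feature_names=features.feature_names,
        )
        mask = None
        if selection is not None:
            mask = fit_low_variance_mask(train_table, **selection)
            train_table = apply_mask(train_table, mask)
            row["n_retained"] = mask.n_retained
            row["retained_idx"] = tuple(np.flatnonzero(mask.retained).tolist())
        model = train(train_table, labels[train_idx], problem,
                      regularization=regularization,
                      class_weight=class_weight, seed=seed)
        model.mask = mask

        test_table = FeatureTable(
            matrix=features.matrix[test_idx],
            roi_index=[features.roi_index[i] for i in test_idx],
            backend_name=features.backend_name,
            feature_names=features.feature_names,
            video_ids=[groups[i] for i in test_idx],
        )
        predictions.extend(predict(model, test_table))
        manifest_rows.append(row)

    manifest = pd.DataFrame(manifest_rows)
    return LoeoResult(problem=problem,
                      class_labels=list(PROBLEM_CLASSES[problem]),
                      predictions=predictions, manifest=manifest)
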