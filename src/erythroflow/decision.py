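"""Video-level cooperative decision rules and their bookkeeping.

A video yields many per-ROI predictions — one per appearance of each cell —
and a single class must be assigned to the whole video.  Three rules are
implemented:

``majority``
    The modal per-ROI label.  Ties are broken first by the larger per-class
    score sum, then by the lower class index.

``percentage_limit`` (two-class only)
    The video is unhealthy (class 1) iff the fraction of ROIs labelled
    unhealthy *strictly* exceeds a limit (e.g. 0.30).  Lowering the limit
    trades false positives for sensitivity: a screening knob.

``max_trustiness``
    The class whose per-ROI normalized scores sum highest over the video.
    Because every ROI's scores sum to one, the per-class sums total the ROI
    count; the winning sum divided by the ROI count is the video's
    normalized score (the bar height in score-profile plots).

``efficiency`` is the video-level overall accuracy: the trace of the
confusion matrix over the total video count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ScoredPrediction
from .errors import DecisionError


@dataclass
class VideoDecision:
    """The aggregated class of one video under a named rule, with evidence."""

    video_id: str
    rule: str
    decided_class: int
    evidence: dict                   # vote counts or score sums per class
    n_rois: int
    parameter: float | None = None   # e.g. the percentage limit
    normalized_score: float | None = None


def _check_nonempty(predictions: list[ScoredPrediction], rule: str) -> str:
    if not predictions:
        raise DecisionError(f"{rule}: no predictions for this video; undecidable")
    return predictions[0].video_id


def _score_sums(predictions: list[ScoredPrediction]) -> np.ndarray:
    return np.sum([p.scores for p in predictions], axis=0)


def majority_vote(predictions: list[ScoredPrediction]) -> VideoDecision:
    """Assign the most voted per-ROI label to the video."""
    video_id = _check_nonempty(predictions, "majority")
    n_classes = len(predictions[0].scores)
    votes = Counter(p.label for p in predictions)
    counts = np.array([votes.get(c, 0) for c in range(n_classes)])
    top = counts.max()
    tied = np.flatnonzero(counts == top)
    if tied.size > 1:
        sums = _score_sums(predictions)[tied]
        tied = tied[np.flatnonzero(sums == sums.max())]
    decided = int(tied[0])  # remaining ties: lowest class index
    return VideoDecision(
        video_id=video_id, rule="majority", decided_class=decided,
        evidence={int(c): int(counts[c]) for c in range(n_classes)},
        n_rois=len(predictions),
    )


def percentage_limit(predictions: list[ScoredPrediction],
                     limit: float = 0.30) -> VideoDecision:
    """Two-class rule: unhealthy iff the unhealthy-ROI fraction exceeds ``limit``.

    Exceedance is strict: exactly ``limit`` stays healthy.
    """
    video_id = _check_nonempty(predictions, "percentage_limit")
    if not 0.0 < limit < 1.0:
        raise DecisionError(f"limit must be in (0, 1), got {limit}")
    if len(predictions[0].scores) != 2:
        raise DecisionError(
            "percentage_limit applies to two-class predictions only")
    n = len(predictions)
    n_unhealthy = sum(p.label == 1 for p in predictions)
    decided = 1 if n_unhealthy / n > limit else 0
    return VideoDecision(
        video_id=video_id, rule="percentage_limit", decided_class=decided,
        evidence={0: n - n_unhealthy, 1: n_unhealthy},
        n_rois=n, parameter=limit,
    )


def max_trustiness(predictions: list[ScoredPrediction]) -> VideoDecision:
    """Assign the class with the highest sum of normalized scores.

    Ties go to the lower class index.  The decision's ``normalized_score`` is
    the winning sum divided by the ROI count, i.e. the mean per-ROI score of
    the winning class.
    """
    video_id = _check_nonempty(predictions, "max_trustiness")
    sums = _score_sums(predictions)
    decided = int(np.argmax(sums))   # argmax breaks ties toward lower index
    return VideoDecision(
        video_id=video_id, rule="max_trustiness", decided_class=decided,
        evidence={int(c): float(sums[c]) for c in range(sums.size)},
        n_rois=len(predictions),
        normalized_score=float(sums[decided] / len(predictions)),
    )


def decide_videos(predictions: list[ScoredPrediction], rule: str,
                  limit: float = 0.30) -> tuple[list[VideoDecision], list[str]]:
    """Group predictions by video and apply one rule to each group.

    Returns the decisions plus the ids of undecidable videos (none here —
    a video with zero predictions simply never appears in the grouping; the
    pipeline reports those separately).
    """
    by_video: dict[str, list[ScoredPrediction]] = {}
    for p in predictions:
        by_video.setdefault(p.video_id, []).append(p)
    decisions, undecidable = [], []
    for video_id in sorted(by_video):
        preds = by_video[video_id]
        try:
            if rule == "majority":
                decisions.append(majority_vote(preds))
            elif rule == "percentage_limit":
                decisions.append(percentage_limit(preds, limit))
            elif rule == "max_trustiness":
                decisions.append(max_trustiness(preds))
            else:
                raise DecisionError(f"unknown rule {rule!r}")
        except DecisionError:
            undecidable.append(video_id)
    return decisions, undecidable


def build_confusion(decisions: list[VideoDecision], truth: dict[str, int],
                    classes: list[int]) -> np.ndarray:
    """Video-level confusion matrix: rows = truth, columns = decided class."""
    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    matrix = np.zeros((k, k), dtype=int)
    for d in decisions:
        if d.video_id not in truth:
            raise DecisionError(f"no truth label for video {d.video_id!r}")
        matrix[index[truth[d.video_id]], index[d.decided_class]] += 1
    return matrix


def efficiency(confusion: np.ndarray) -> float:
    """Overall video-level accuracy: trace over total, as a fraction.

    Kept at full precision; use :func:`efficiency_percent` for the integer
    percentage used in displays.
    """
    confusion = np.asarray(confusion)
    total = confusion.sum()
    if total == 0:
        raise DecisionError("efficiency undefined for an empty confusion matrix")
    return float(np.trace(confusion) / total)


def efficiency_percent(confusion: np.ndarray) -> int:
    """Efficiency as the integer percentage shown in reports."""
    return int(round(100.0 * efficiency(confusion)))


def decisions_frame(decisions: list[VideoDecision],
                    truth: dict[str, int] | None = None) -> pd.DataFrame:
    """Tabulate decisions (one row per video) for CSV export."""
    recs = []
    for d in decisions:
        rec = {
            "video_id": d.video_id, "rule": d.rule,
            "parameter": d.parameter, "decided": d.decided_class,
            "n_rois": d.n_rois, "normalized_score": d.normalized_score,
            "evidence": repr(d.evidence),
        }
        if truth is not None:
            rec["truth"] = truth.get(d.video_id)
        recs.append(rec)
    return pd.DataFrame(recs)


def score_profile(decisions: list[VideoDecision],
                  truth: dict[str, int]) -> pd.DataFrame:
    """Per-video (assigned class, normalized score) pairs for bar plotting.

    For rules without score sums the normalized score falls back to the
    winning vote fraction.
    """
    recs = []
    for d in decisions:
        score = d.normalized_score
        if score is None:
            score = d.evidence[d.decided_class] / d.n_rois
        recs.append({"video_id": d.video_id, "assigned": d.decided_class,
                     "truth": truth.get(d.video_id), "score": float(score)})
    return pd.DataFrame(recs)
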