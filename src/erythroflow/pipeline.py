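"""End-to-end orchestration: simulate → preprocess → detect → extract →
select → classify (LOEO) → decide.

One :class:`RunConfig` drives the whole run; all randomness flows from its
single seed (the synthetic cohort derives per-video seeds from it).  The run
report contains, for every decision rule evaluated, the video-level
confusion matrix and its efficiency, together with the fold manifest, the
per-video/side ROI counts (with their internal consistency identities
enforced) and the feature-reduction factor — every number in it is
recomputable from the persisted intermediates.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import decision as decision_mod
from .classify import run_loeo
from .errors import ConfigurationError, EstimationError
from .features import extract_features, get_backend
from .localization import detect_video, extract_rois, filter_rois, match_detections
from .synthetic import (CONDITION_LABELS, CONDITIONS, GroundTruth,
                        SyntheticConfig, generate_cohort)
from .video_io import VideoRecord, crop_to_barrier_region, estimate_barrier_x, read_video

logger = logging.getLogger(__name__)

DISEASE_CONDITIONS = ("SCD", "THAL", "HS")


@dataclass
class RunConfig:
    """All stage parameters of one reproducible pipeline run."""

    seed: int = 0
    out_dir: str | None = None
    # --- input: either a synthetic cohort spec or a manifest of videos
    cohort: dict[str, int] = field(
        default_factory=lambda: {"healthy": 3, "SCD": 1, "THAL": 1, "HS": 1})
    synthetic: dict = field(default_factory=dict)   # SyntheticConfig overrides
    input_manifest: str | None = None
    # --- preprocessing
    barrier: str = "metadata"        # "metadata" | "auto"
    half_width: int | None = None    # default: 3 x mean cell diameter
    # --- detection / ROI extraction
    r_min: int = 5
    r_max: int = 11
    sensitivity: float = 0.35
    roi_size: int = 32
    side: str = "after"
    min_score: float = 0.40
    barrier_margin: int = 16   # ~2 cell diameters past the band
    # --- features / selection / classification
    backend: str = "handcrafted"
    weights_path: str | None = None
    selection: dict | None = None    # e.g. {"mode": "target_factor", "value": 50}
    problem: str = "two_class"
    regularization: float = 1.0
    class_weight: str | None = None
    # --- decision rules: list of (rule, parameter) pairs; None = per-problem default
    rules: list | None = None
    keep_intermediates: bool = True

    def resolved_rules(self) -> list[tuple[str, float | None]]:
        if self.rules is not None:
            return [tuple(r) for r in self.rules]
        if self.problem == "two_class":
            return [("majority", None), ("percentage_limit", 0.30),
                    ("percentage_limit", 0.40), ("max_trustiness", None)]
        return [("majority", None), ("max_trustiness", None)]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def condition_to_label(condition: str, problem: str) -> int:
    if condition not in CONDITIONS:
        raise ConfigurationError(f"unknown condition {condition!r}")
    if problem == "two_class":
        return 0 if condition == "healthy" else 1
    return CONDITION_LABELS[condition]


def build_count_table(video_conditions: dict[str, str],
                      roi_counts: dict[str, int]) -> pd.DataFrame:
    """Per-condition bookkeeping of videos and after-barrier ROI counts.

    One row per condition present, one ``RHHA`` row aggregating the disease
    conditions, and a ``Total`` row — the layout used for slit-barrier cohort
    accounting.
    """
    rows = []
    for cond in CONDITIONS:
        vids = [v for v, c in video_conditions.items() if c == cond]
        if not vids and cond != "healthy":
            continue
        rows.append({
            "sample": "Control" if cond == "healthy" else cond,
            "n_videos": len(vids),
            "n_rois_after": int(sum(roi_counts.get(v, 0) for v in vids)),
        })
    disease = [r for r in rows if r["sample"] in DISEASE_CONDITIONS]
    rhha = {"sample": "RHHA",
            "n_videos": sum(r["n_videos"] for r in disease),
            "n_rois_after": sum(r["n_rois_after"] for r in disease)}
    total = {"sample": "Total",
             "n_videos": sum(r["n_videos"] for r in rows),
             "n_rois_after": sum(r["n_rois_after"] for r in rows)}
    control = [r for r in rows if r["sample"] == "Control"]
    table = pd.DataFrame([total] + control + [rhha] + disease)
    verify_count_identities(table)
    return table


def verify_count_identities(table: pd.DataFrame) -> None:
    """Enforce the internal consistency of a count table.

    Control + RHHA must equal Total, and the disease conditions must sum to
    RHHA, for both video and ROI counts.
    """
    t = table.set_index("sample")
    for col in ("n_videos", "n_rois_after"):
        total = int(t.loc["Total", col])
        control = int(t.loc["Control", col]) if "Control" in t.index else 0
        rhha = int(t.loc["RHHA", col]) if "RHHA" in t.index else 0
        disease_sum = int(sum(t.loc[s, col] for s in DISEASE_CONDITIONS
                              if s in t.index))
        if control + rhha != total:
            raise ConfigurationError(
                f"count identity violated: Control+RHHA != Total for {col} "
                f"({control}+{rhha} != {total})")
        if disease_sum != rhha:
            raise ConfigurationError(
                f"count identity violated: SCD+THAL+HS != RHHA for {col} "
                f"({disease_sum} != {rhha})")


def load_cohort_from_manifest(manifest_path: str | Path
                              ) -> list[tuple[VideoRecord, GroundTruth | None]]:
    """Read a cohort manifest CSV (video_id, path, condition) and its videos."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    cohort = []
    for _, rec in manifest.iterrows():
        video = read_video(rec["path"])
        video.video_id = str(rec["video_id"])
        video.condition_label = rec.get("condition", video.condition_label)
        truth_path = manifest_path.parent / f"{video.video_id}.truth.json"
        truth = GroundTruth.from_json(truth_path) if truth_path.exists() else None
        cohort.append((video, truth))
    return cohort


def _default_half_width(config: RunConfig) -> int:
    radius = SyntheticConfig(**config.synthetic).cell_radius_px[0] \
        if config.input_manifest is None else 8.0
    return int(round(3 * 2 * radius))


def run_pipeline(config: RunConfig,
                 cohort: list[tuple[VideoRecord, GroundTruth | None]] | None = None
                 ) -> dict:
    """Execute the full pipeline and return the run report.

    ``cohort`` may be supplied directly (e.g. a pre-generated synthetic
    cohort); otherwise it is simulated from ``config.cohort`` /
    ``config.synthetic`` or loaded from ``config.input_manifest``.
    """
    t_start = time.monotonic()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_json(out_dir / "run_config.json")

    # --- stage 1: inputs
    if cohort is None:
        if config.input_manifest:
            cohort = load_cohort_from_manifest(config.input_manifest)
        else:
            base = SyntheticConfig(**config.synthetic)
            cohort = generate_cohort(config.cohort, base, seed=config.seed)
    logger.info("cohort of %d videos", len(cohort))

    half_width = config.half_width or _default_half_width(config)
    video_conditions: dict[str, str] = {}
    roi_counts_after: dict[str, int] = {}
    roi_counts_before: dict[str, int] = {}
    all_rois = []
    detection_truth_stats = []

    for video, truth in cohort:
        if video.condition_label is None:
            raise ConfigurationError(f"video {video.video_id} has no condition label")
        video_conditions[video.video_id] = video.condition_label

        # --- stage 2: preprocessing (barrier estimate + crop)
        try:
            barrier_x = (estimate_barrier_x(video) if config.barrier == "auto"
                         else video.barrier_x)
            if barrier_x is None:
                barrier_x = estimate_barrier_x(video)
        except EstimationError as exc:
            raise EstimationError(
                f"stage preprocess failed on video {video.video_id}: {exc}") from exc
        cropped = crop_to_barrier_region(video, half_width, barrier_x=barrier_x)
        offset = barrier_x - cropped.barrier_x

        # --- stage 3: detection + ROI extraction
        detections = detect_video(cropped, config.r_min, config.r_max,
                                  config.sensitivity)
        rois = extract_rois(cropped, detections, config.roi_size,
                            barrier_x=cropped.barrier_x)
        kept = filter_rois(rois, side=config.side, min_score=config.min_score,
                           barrier_x=cropped.barrier_x,
                           barrier_margin=config.barrier_margin)
        roi_counts_after[video.video_id] = sum(r.side == "after" for r in rois)
        roi_counts_before[video.video_id] = sum(r.side == "before" for r in rois)
        all_rois.extend(kept)

        if truth is not None and len(truth.positions):
            shifted = truth.positions.copy()
            shifted["col"] = shifted["col"] - offset
            shifted = shifted[(shifted["col"] >= 0)
                              & (shifted["col"] < cropped.frames.shape[2])]
            stats = match_detections(detections, shifted)
            stats["video_id"] = video.video_id
            detection_truth_stats.append(stats)

    counts_table = build_count_table(video_conditions, roi_counts_after)

    # videos contributing no ROI on the analysed side are undecidable
    with_rois = {r.video_id for r in all_rois}
    undecidable = sorted(set(video_conditions) - with_rois)
    if undecidable:
        logger.warning("videos with no %s-barrier ROIs (undecidable): %s",
                       config.side, undecidable)

    # --- stage 4: features
    backend = get_backend(config.backend, config.weights_path)
    features = extract_features(all_rois, backend)

    # --- stage 5+6: per-fold selection + LOEO classification
    video_labels = {v: condition_to_label(c, config.problem)
                    for v, c in video_conditions.items() if v in with_rois}
    loeo = run_loeo(features, video_labels, config.problem,
                    selection=config.selection,
                    regularization=config.regularization,
                    class_weight=config.class_weight, seed=config.seed)

    reduction = None
    if config.selection is not None:
        done = loeo.manifest[~loeo.manifest["skipped"]]
        reduction = float(features.n_features / done["n_retained"].mean())

    # --- stage 7: cooperative decisions per rule
    classes = loeo.class_labels
    rules_report = {}
    decision_frames = {}
    for rule, param in config.resolved_rules():
        if rule == "percentage_limit" and config.problem != "two_class":
            logger.warning("skipping percentage_limit: two-class rule only")
            continue
        key = rule if param is None else f"{rule}@{param:.2f}"
        decisions, failed = decision_mod.decide_videos(
            loeo.predictions, rule, limit=param if param is not None else 0.30)
        confusion = decision_mod.build_confusion(decisions, video_labels, classes)
        rules_report[key] = {
            "confusion": confusion.tolist(),
            "efficiency": decision_mod.efficiency(confusion),
            "efficiency_percent": decision_mod.efficiency_percent(confusion),
            "n_videos": int(confusion.sum()),
            "undecidable": failed,
        }
        decision_frames[key] = decision_mod.decisions_frame(decisions, video_labels)

    report = {
        "config": asdict(config),
        "n_videos": len(cohort),
        "undecidable_videos": undecidable,
        "counts_table": counts_table.to_dict(orient="records"),
        "roi_counts_before": roi_counts_before,
        "roi_counts_after": roi_counts_after,
        "loeo": {
            "n_folds": int(len(loeo.manifest)),
            "n_skipped_folds": int(loeo.manifest["skipped"].sum()),
            "mean_training_rows": loeo.mean_training_rows,
            "per_roi_accuracy": loeo.per_roi_accuracy(video_labels),
            "n_rois": len(loeo.predictions),
        },
        "n_features": features.n_features,
        "feature_backend": features.backend_name,
        "reduction_factor": reduction,
        "rules": rules_report,
    }
    if detection_truth_stats:
        recalls = [s["recall"] for s in detection_truth_stats
                   if np.isfinite(s["recall"])]
        errors = [s["mean_center_error_px"] for s in detection_truth_stats
                  if np.isfinite(s["mean_center_error_px"])]
        report["detection_vs_truth"] = {
            "mean_recall": float(np.mean(recalls)) if recalls else None,
            "mean_center_error_px": float(np.mean(errors)) if errors else None,
            "per_video": detection_truth_stats,
        }

    if out_dir:
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=float)
        if config.keep_intermediates:
            features.to_csv(out_dir / "features.csv")
            loeo.predictions_frame().to_csv(out_dir / "predictions.csv", index=False)
            manifest = loeo.manifest.copy()
            manifest["retained_idx"] = manifest["retained_idx"].map(
                lambda v: "" if v is None else ";".join(map(str, v)))
            manifest.to_csv(out_dir / "fold_manifest.csv", index=False)
            counts_table.to_csv(out_dir / "counts_table.csv", index=False)
            for key, frame in decision_frames.items():
                frame.to_csv(out_dir / f"decisions_{key.replace('@', '_')}.csv",
                             index=False)
    logger.info("pipeline finished in %.1f s", time.monotonic() - t_start)
    return report
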