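"""Per-frame cell detection and fixed-size ROI extraction.

Cells are localized frame by frame with the circular Hough transform on a
Canny edge map — an approach suited to the quasi-circular projections of red
blood cells.  No tracking is performed: the same physical cell yields one
ROI per frame in which it is detected, which is exactly the sampling the
downstream cooperative decision rules expect.  Each ROI is tagged as lying
*before* or *after* the barrier; the discriminative analysis runs on
after-barrier ROIs, where healthy cells have recovered a compact shape and
diseased ones have not.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .errors import FormatError
from .video_io import VideoRecord


@dataclass
class CellDetection:
    """One circular Hough detection in one frame."""

    frame_index: int
    center: tuple[int, int]        # (row, col)
    radius: int
    accumulator_score: float       # normalized Hough vote fraction, ~[0, 1]


@dataclass
class RoiSample:
    """A fixed-size square crop around one detected cell."""

    image: np.ndarray
    video_id: str
    frame_index: int
    center: tuple[int, int]        # (row, col) in frame coordinates
    side: str                      # "before" | "after"
    detection_score: float

    @property
    def roi_id(self) -> str:
        r, c = self.center
        return f"{self.video_id}:{self.frame_index}:{r}:{c}"


def detect_cells(frame: np.ndarray, r_min: int, r_max: int,
                 sensitivity: float = 0.25,
                 canny_sigma: float = 1.4) -> list[CellDetection]:
    """Detect quasi-circular cells in a single grayscale frame.

    Edge pixels vote in a circular Hough accumulator over integer radii in
    ``[r_min, r_max]``; accumulator values are normalized by circle perimeter
    so a complete circle scores ~1.  Peaks below ``sensitivity`` are
    discarded and non-maximum suppression removes any detection whose centre
    lies within ``r_min`` px of a stronger one.  Detections are returned by
    descending score, ties broken by (row, col).
    """
    if r_min > r_max or r_min < 1:
        raise ValueError(f"invalid radius range [{r_min}, {r_max}]")
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D grayscale")
    img = frame.astype(float)
    if img.max() > 1.0:
        img = img / 255.0
    edges = canny(img, sigma=canny_sigma)
    if not edges.any():
        return []
    radii = np.arange(r_min, r_max + 1)
    accum = hough_circle(edges, radii)  # normalized by 2*pi*r
    scores, cxs, cys, rads = hough_circle_peaks(
        accum, radii,
        min_xdistance=r_min, min_ydistance=r_min,
        threshold=sensitivity,
        total_num_peaks=200,
    )
    if len(scores) == 0:
        return []
    # greedy NMS across radius layers; deterministic order
    order = sorted(range(len(scores)),
                   key=lambda i: (-scores[i], cys[i], cxs[i]))
    kept: list[CellDetection] = []
    h, w = frame.shape
    for i in order:
        r, c = int(cys[i]), int(cxs[i])
        if not (0 <= r < h and 0 <= c < w):
            continue
        if any(np.hypot(r - d.center[0], c - d.center[1]) < r_min for d in kept):
            continue
        kept.append(CellDetection(
            frame_index=-1, center=(r, c), radius=int(rads[i]),
            accumulator_score=float(min(scores[i], 1.0)),
        ))
    return kept


def detect_video(video: VideoRecord, r_min: int, r_max: int,
                 sensitivity: float = 0.25) -> list[list[CellDetection]]:
    """Run :func:`detect_cells` on every frame; fills in frame indices."""
    per_frame = []
    for t, frame in enumerate(video.frames):
        dets = detect_cells(frame, r_min, r_max, sensitivity)
        for d in dets:
            d.frame_index = t
        per_frame.append(dets)
    return per_frame


def extract_rois(video: VideoRecord, detections: list[list[CellDetection]],
                 roi_size: int, barrier_x: int | None = None) -> list[RoiSample]:
    """Extract one fixed-size square crop per detection.

    ``side`` is ``after`` iff the centre column is strictly greater than
    ``barrier_x``.  Crops that extend past the frame are zero-padded so every
    ROI is exactly ``roi_size`` × ``roi_size``.
    """
    if roi_size <= 0 or roi_size % 2:
        raise ValueError(f"roi_size must be a positive even count, got {roi_size}")
    if barrier_x is None:
        barrier_x = video.barrier_x
    if barrier_x is None:
        raise ValueError("barrier_x unknown: pass it or set it on the video record")
    half = roi_size // 2
    h, w = video.frame_shape
    rois: list[RoiSample] = []
    for frame_dets in detections:
        for det in frame_dets:
            t = det.frame_index
            r, c = det.center
            crop = np.zeros((roi_size, roi_size), dtype=video.frames.dtype)
            r0, r1 = r - half, r + half
            c0, c1 = c - half, c + half
            sr0, sr1 = max(r0, 0), min(r1, h)
            sc0, sc1 = max(c0, 0), min(c1, w)
            crop[sr0 - r0:sr1 - r0, sc0 - c0:sc1 - c0] = \
                video.frames[t, sr0:sr1, sc0:sc1]
            rois.append(RoiSample(
                image=crop,
                video_id=video.video_id,
                frame_index=t,
                center=(r, c),
                side="after" if c > barrier_x else "before",
                detection_score=det.accumulator_score,
            ))
    return rois


def filter_rois(rois: list[RoiSample], side: str = "after",
                min_score: float = 0.0, barrier_x: int | None = None,
                barrier_margin: int = 0) -> list[RoiSample]:
    """Order-preserving subset by barrier side, score and barrier distance.

    ``side`` is one of ``before``/``after``/``both``.  The default pipeline
    keeps after-barrier ROIs only, where shape recovery separates classes.
    When ``barrier_x`` is given with a positive ``barrier_margin``, ROIs whose
    centre lies within that many columns of the band are also dropped: the
    band vicinity is crowded with spurious edge responses and with cells
    whose shape has not yet had room to relax.
    """
    if side not in ("before", "after", "both"):
        raise ValueError(f"side must be before/after/both, got {side!r}")
    kept = [roi for roi in rois
            if (side == "both" or roi.side == side)
            and roi.detection_score >= min_score]
    if barrier_x is not None and barrier_margin > 0:
        kept = [roi for roi in kept
                if abs(roi.center[1] - barrier_x) > barrier_margin]
    return kept


def match_detections(detections: list[list[CellDetection]],
                     truth_positions, max_dist: float = 4.0,
                     exclude_overlapped: bool = True,
                     regions: tuple[str, ...] = ("pre", "post"),
                     max_eccentricity: float = 0.6) -> dict:
    """Score detections against generator ground truth.

    Considers truth positions outside the slit band (quasi-circular
    projections only: rendered eccentricity ≤ ``max_eccentricity``), not
    overlapped, and matches each greedily to the nearest detection in the
    same frame within ``max_dist`` px.  Returns recall, mean/max centre
    error and the match count.
    """
    truth = truth_positions
    mask = truth["region"].isin(regions) & (truth["eccentricity"] <= max_eccentricity)
    if exclude_overlapped:
        mask &= ~truth["overlapped"]
    truth = truth[mask]
    n_truth = 0
    errors = []
    by_frame = {t: [d.center for d in dets] for t, dets in enumerate(detections)}
    for frame, group in truth.groupby("frame"):
        centers = by_frame.get(int(frame), [])
        used = [False] * len(centers)
        for _, row in group.iterrows():
            n_truth += 1
            best, best_d = -1, np.inf
            for i, (r, c) in enumerate(centers):
                if used[i]:
                    continue
                d = np.hypot(r - row["row"], c - row["col"])
                if d < best_d:
                    best, best_d = i, d
            if best >= 0 and best_d <= max_dist:
                used[best] = True
                errors.append(best_d)
    recall = len(errors) / n_truth if n_truth else float("nan")
    return {
        "n_truth": n_truth,
        "n_matched": len(errors),
        "recall": recall,
        "mean_center_error_px": float(np.mean(errors)) if errors else float("nan"),
        "max_center_error_px": float(np.max(errors)) if errors else float("nan"),
    }


def write_rois(rois: list[RoiSample], out_dir: str | Path) -> Path:
    """Persist a ROI bundle: PNG crops plus an index CSV. Lossless round-trip."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index_path = out_dir / "index.csv"
    with open(index_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "video_id", "frame", "row", "col",
                        "side", "score"])
        for i, roi in enumerate(rois):
            name = f"roi_{i:06d}.png"
            img = roi.image
            if img.dtype != np.uint8:
                img = np.clip(img * 255.0, 0, 255).astype(np.uint8)
            iio.imwrite(out_dir / name, img)
            writer.writerow([name, roi.video_id, roi.frame_index,
                             roi.center[0], roi.center[1], roi.side,
                             f"{roi.detection_score:.6f}"])
    return out_dir


def read_rois(bundle_dir: str | Path) -> list[RoiSample]:
    """Read back a ROI bundle written by :func:`write_rois`."""
    bundle_dir = Path(bundle_dir)
    index_path = bundle_dir / "index.csv"
    if not index_path.exists():
        raise FormatError(f"not a ROI bundle (missing index.csv): {bundle_dir}")
    rois = []
    with open(index_path) as fh:
        for rec in csv.DictReader(fh):
            rois.append(RoiSample(
                image=iio.imread(bundle_dir / rec["filename"]),
                video_id=rec["video_id"],
                frame_index=int(rec["frame"]),
                center=(int(rec["row"]), int(rec["col"])),
                side=rec["side"],
                detection_score=float(rec["score"]),
            ))
    return rois
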