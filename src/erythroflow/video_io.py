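"""Reading, writing and cropping of slit-barrier frame stacks.

Videos are handled as in-memory :class:`VideoRecord` objects.  On disk a video
is either a multi-page TIFF, a directory of lexicographically ordered PNG/TIFF
frames, or (read-only, discouraged) an AVI.  A sidecar JSON file carries
acquisition metadata: ``{"video_id", "fps", "condition", "barrier_x"}``.

The preprocessing step mirrors typical practice for slit-barrier recordings:
the full field of view contains channel walls and pillar matrices that confuse
cell detection, so each video is cropped to a window of columns centred on the
barrier.  When the barrier column is not known from metadata it can be
estimated from the temporal-mean intensity profile (the barrier's
micro-constrictions are the darkest persistent vertical structure in the
scene).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter1d

from .errors import EstimationError, FormatError

logger = logging.getLogger(__name__)

_FRAME_EXTENSIONS = (".png", ".tif", ".tiff")


@dataclass
class VideoRecord:
    """An ordered grayscale frame stack plus acquisition metadata.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)``, dtype uint8 (gray
        levels) or float in [0, 1].  All frames share one shape.
    video_id
        Stable identifier used to group ROIs and predictions.
    fps
        Acquisition rate in frames per second; must be positive.
    condition_label
        Optional condition tag (``healthy``/``SCD``/``THAL``/``HS``).
    barrier_x
        Column index of the slit-barrier band centre, if known.
    source_path
        Where the video was read from, for provenance.
    """

    frames: np.ndarray
    video_id: str = "video"
    fps: float = 85.0
    condition_label: str | None = None
    barrier_x: int | None = None
    source_path: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FormatError(
                f"frames must be a (n, h, w) stack, got shape {self.frames.shape}"
            )
        if self.fps <= 0:
            raise FormatError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return int(self.frames.shape[1]), int(self.frames.shape[2])

    def metadata(self) -> dict:
        return {
            "video_id": self.video_id,
            "fps": self.fps,
            "condition": self.condition_label,
            "barrier_x": None if self.barrier_x is None else int(self.barrier_x),
        }


def _sidecar_path(path: Path) -> Path:
    if path.is_dir():
        return path / "metadata.json"
    return path.with_suffix(".json")


def write_video(video: VideoRecord, path: str | Path) -> Path:
    """Write ``video`` as a multi-page TIFF (``*.tif``) or a PNG frame
    directory (any other path), plus a metadata sidecar JSON.

    Lossless formats only; pixel values round-trip exactly.
    """
    path = Path(path)
    frames = video.frames
    if frames.dtype != np.uint8:
        frames = np.clip(np.asarray(frames, dtype=float) * 255.0, 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, frames)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(frames):
            iio.imwrite(path / f"frame_{i:05d}.png", frame)
    with open(_sidecar_path(path), "w") as fh:
        json.dump(video.metadata(), fh, indent=1, sort_keys=True)
    return path


def _read_frame_dir(path: Path) -> np.ndarray:
    files = sorted(
        p for p in path.iterdir()
        if p.suffix.lower() in _FRAME_EXTENSIONS and not p.name.startswith(".")
    )
    if not files:
        raise FormatError(f"no frame images found in directory {path}")
    frames = []
    shape = None
    for p in files:
        img = iio.imread(p)
        if img.ndim == 3:  # collapse RGB(A) to gray
            img = img[..., :3].mean(axis=-1).astype(img.dtype)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise FormatError(
                f"frame {p.name} has shape {img.shape}, expected {shape}"
            )
        frames.append(img)
    return np.stack(frames)


def read_video(path: str | Path) -> VideoRecord:
    """Read a video from a multi-page TIFF, a frame directory, or an AVI.

    Metadata is taken from the sidecar JSON when present.  AVI containers are
    typically lossy; a warning is logged because downstream results are then
    not bit-reproducible.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"video path does not exist: {path}")
    if path.is_dir():
        frames = _read_frame_dir(path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        try:
            frames = tifffile.imread(path)
        except Exception as exc:  # pragma: no cover - corrupt file path
            raise FormatError(f"could not read TIFF stack {path}: {exc}") from exc
        if frames.ndim == 2:
            frames = frames[None]
    elif path.suffix.lower() == ".avi":
        logger.warning("AVI container %s may be lossy; prefer TIFF/PNG", path)
        try:
            frames = np.stack([f if f.ndim == 2 else f[..., :3].mean(-1)
                               for f in iio.imiter(path)])
        except Exception as exc:
            raise FormatError(f"could not decode AVI {path}: {exc}") from exc
    else:
        raise FormatError(f"unsupported video container: {path}")
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise FormatError(f"no frames decoded from {path}")

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    return VideoRecord(
        frames=frames,
        video_id=meta.get("video_id", path.stem if not path.is_dir() else path.name),
        fps=float(meta.get("fps", 85.0)),
        condition_label=meta.get("condition"),
        barrier_x=meta.get("barrier_x"),
        source_path=str(path),
    )


def estimate_barrier_x(video: VideoRecord, smooth_sigma: float = 2.0,
                       min_contrast: float = 4.0, max_frames: int = 100) -> int:
    """Estimate the slit-barrier column from the temporal-mean column profile.

    The barrier is the darkest persistent vertical structure: averaging over
    time suppresses moving cells, and the minimum of the column-mean profile
    (smoothed along columns with a Gaussian of ``smooth_sigma`` px) marks the
    band centre.  ``min_contrast`` is the minimum peak-to-background contrast
    in gray levels below which the profile is declared flat.

    Raises
    ------
    EstimationError
        If no sufficiently dark vertical structure exists.
    """
    if video.n_frames < 1:
        raise EstimationError("cannot estimate barrier on an empty video")
    step = max(1, video.n_frames // max_frames)
    sample = video.frames[::step].astype(float)
    profile = sample.mean(axis=(0, 1))
    profile = gaussian_filter1d(profile, smooth_sigma)
    median = float(np.median(profile))
    contrast = float(median - profile.min())
    # flat-profile guard: the dip must stand out both absolutely and against
    # the profile's own fluctuation level (robust MAD scale)
    mad = float(np.median(np.abs(profile - median)))
    floor = max(min_contrast, 5.0 * 1.4826 * mad)
    if contrast < floor:
        raise EstimationError(
            f"no barrier-like vertical structure found (dip {contrast:.2f} "
            f"gray levels < required {floor:.2f})"
        )
    return int(np.argmin(profile))


def crop_to_barrier_region(video: VideoRecord, half_width_px: int,
                           barrier_x: int | None = None) -> VideoRecord:
    """Crop all frames to columns ``[barrier_x - half_width, barrier_x + half_width]``.

    ``barrier_x`` defaults to the record's metadata value.  The returned
    record has ``barrier_x`` remapped into cropped coordinates; all other
    metadata is preserved.  A window extending past the frame bounds is
    clipped with a logged warning.
    """
    if barrier_x is None:
        barrier_x = video.barrier_x
    if barrier_x is None:
        raise EstimationError(
            "barrier_x unknown; pass it explicitly or call estimate_barrier_x first"
        )
    if half_width_px <= 0:
        raise FormatError(f"half_width_px must be positive, got {half_width_px}")
    width = video.frames.shape[2]
    lo = barrier_x - half_width_px
    hi = barrier_x + half_width_px
    if lo < 0 or hi > width:
        logger.warning(
            "crop window [%d, %d] exceeds frame width %d for %s; clipping",
            lo, hi, width, video.video_id,
        )
        lo = max(lo, 0)
        hi = min(hi, width)
    cropped = video.frames[:, :, lo:hi]
    return replace(video, frames=cropped, barrier_x=int(barrier_x - lo))
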