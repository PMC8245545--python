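"""ROI feature coding through pluggable backends.

Two backends code each fixed-size ROI crop into a fixed-length numeric
descriptor vector:

``handcrafted``
    A deterministic shape/intensity descriptor set (area, perimeter,
    circularity, eccentricity, solidity, the 7 Hu moment invariants,
    foreground intensity statistics and a radial intensity profile) computed
    on an Otsu-thresholded mask of the central cell.  Runs everywhere with no
    model weights; its descriptors directly encode the shape-recovery signal
    that separates conditions.

``alexnet_pool5``
    Transfer-learning coding: the flattened activation of the third
    max-pooling layer ("pool5", 256x6x6 = 9216 values) of an AlexNet with
    frozen pretrained weights.  Weights must be supplied as a local file; the
    package never downloads them, and the backend raises a capability error
    when torch or the weights are unavailable, pointing at the handcrafted
    backend instead.  No fine-tuning ever occurs.

Downstream stages are backend-agnostic: swapping the backend changes the
number of columns of the :class:`FeatureTable`, never its row alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .errors import BackendUnavailableError
from .localization import RoiSample

N_RADIAL_BINS = 6

HANDCRAFTED_FEATURE_NAMES = (
    ["area", "perimeter", "circularity", "eccentricity", "solidity"]
    + [f"hu{i}" for i in range(1, 8)]
    + ["fg_mean", "fg_std", "fg_skew"]
    + [f"radial_{i}" for i in range(N_RADIAL_BINS)]
)


@dataclass
class FeatureTable:
    """ROI-aligned descriptor matrix with backend provenance.

    ``matrix`` is ``n_rois x n_features`` with no missing values;
    ``roi_index`` holds one identifier per row in matching order.
    """

    matrix: np.ndarray
    roi_index: list[str]
    backend_name: str
    feature_names: list[str] | None = None
    video_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.matrix.shape[0] != len(self.roi_index):
            raise ValueError("roi_index length must equal the number of rows")
        if not np.isfinite(self.matrix).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_rois(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        names = self.feature_names or [f"f{i}" for i in range(self.n_features)]
        df = pd.DataFrame(self.matrix, columns=names)
        df.insert(0, "roi_id", self.roi_index)
        if self.video_ids is not None:
            df.insert(1, "video_id", self.video_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, backend_name: str = "stored") -> "FeatureTable":
        df = pd.read_csv(path)
        meta_cols = [c for c in ("roi_id", "video_id") if c in df.columns]
        feats = df.drop(columns=meta_cols)
        return cls(
            matrix=feats.to_numpy(dtype=float),
            roi_index=list(df["roi_id"].astype(str)),
            backend_name=backend_name,
            feature_names=list(feats.columns),
            video_ids=list(df["video_id"]) if "video_id" in df else None,
        )


def _radial_profile(img: np.ndarray, n_bins: int = N_RADIAL_BINS) -> np.ndarray:
    h, w = img.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    rr = np.hypot(yy - cy, xx - cx)
    r_max = min(h, w) / 2.0
    out = np.zeros(n_bins)
    edges = np.linspace(0.0, r_max, n_bins + 1)
    for i in range(n_bins):
        sel = (rr >= edges[i]) & (rr < edges[i + 1])
        out[i] = img[sel].mean() if sel.any() else 0.0
    return out


def handcrafted_descriptors(roi_image: np.ndarray) -> np.ndarray:
    """Shape + intensity descriptor vector of a single square grayscale crop.

    The cell mask is the largest Otsu-foreground connected component nearest
    the crop centre (cells are darker than background).  The fixed descriptor
    order is :data:`HANDCRAFTED_FEATURE_NAMES`; a crop with no foreground
    yields an all-zero shape block with whole-crop intensity statistics, so
    blank ROIs remain well-defined.
    """
    img = np.asarray(roi_image, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("ROI must be a square 2-D grayscale crop")
    if img.max() > 1.0:
        img = img / 255.0
    h, w = img.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    shape_block = np.zeros(12)
    mask = None
    if np.ptp(img) > 1e-9:
        thresh = threshold_otsu(img)
        fg = img < thresh  # cells absorb: darker than background
        if fg.any():
            labels = cc_label(fg)
            props = regionprops(labels)
            # component whose centroid is nearest the crop centre; ties by size
            props.sort(key=lambda p: (np.hypot(p.centroid[0] - cy,
                                               p.centroid[1] - cx), -p.area))
            best = props[0]
            if best.area >= 5:
                mask = labels == best.label
                perimeter = max(best.perimeter, 1e-9)
                circularity = 4.0 * np.pi * best.area / perimeter ** 2
                shape_block = np.concatenate([
                    [best.area, best.perimeter, circularity,
                     best.eccentricity, best.solidity],
                    best.moments_hu,
                ])

    if mask is not None and mask.sum() >= 2:
        vals = img[mask]
        skew = stats.skew(vals) if np.ptp(vals) > 1e-12 else 0.0
        intensity = np.array([vals.mean(), vals.std(), skew])
    else:
        vals = img.ravel()
        skew = stats.skew(vals) if np.ptp(vals) > 1e-12 else 0.0
        intensity = np.array([vals.mean(), vals.std(), skew])

    return np.concatenate([shape_block, intensity, _radial_profile(img)])


class HandcraftedBackend:
    """Deterministic shape-descriptor backend (no model weights)."""

    name = "handcrafted_v1"
    feature_names = list(HANDCRAFTED_FEATURE_NAMES)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def encode(self, image: np.ndarray) -> np.ndarray:
        return handcrafted_descriptors(image)


#: AlexNet feature-extractor geometry: (kind, kernel, stride, padding).
#: Three max-pool layers; the flattened output of the last one is "pool5".
_ALEXNET_LAYERS = [
    ("conv", 11, 4, 2),   # conv1, 64 ch
    ("pool", 3, 2, 0),    # maxpool 1
    ("conv", 5, 1, 2),    # conv2, 192 ch
    ("pool", 3, 2, 0),    # maxpool 2
    ("conv", 3, 1, 1),    # conv3, 384 ch
    ("conv", 3, 1, 1),    # conv4, 256 ch
    ("conv", 3, 1, 1),    # conv5, 256 ch
    ("pool", 3, 2, 0),    # maxpool 3  ("pool5")
]
_ALEXNET_INPUT_SIZE = 224
_ALEXNET_POOL5_CHANNELS = 256


def alexnet_pool5_dim(input_size: int = _ALEXNET_INPUT_SIZE) -> int:
    """Flattened pool5 dimensionality from the architecture arithmetic.

    Walks the conv/pool geometry with the standard output-size recurrence
    ``floor((n + 2p - k) / s) + 1`` and multiplies by the channel count.
    """
    n = input_size
    for _kind, k, s, p in _ALEXNET_LAYERS:
        n = (n + 2 * p - k) // s + 1
    return _ALEXNET_POOL5_CHANNELS * n * n


class AlexNetPool5Backend:
    """Transfer-learning backend: frozen AlexNet, flattened pool5 activation.

    The grayscale crop is replicated to three channels, bilinearly resized to
    the network input size and scaled to [0, 1]; the weights file must exist
    locally — nothing is downloaded.
    """

    name = "alexnet_pool5"
    feature_names = None  # anonymous CNN activations

    def __init__(self, weights_path: str | Path | None):
        if weights_path is None or not Path(weights_path).exists():
            raise BackendUnavailableError(
                "AlexNet weights file not found (no download is ever attempted). "
                "Pass a local weights path, or use the handcrafted backend: "
                "extract_features(rois, HandcraftedBackend())."
            )
        try:
            import torch  # noqa: F401
            import torchvision
        except ImportError as exc:
            raise BackendUnavailableError(
                "torch/torchvision are not installed; install the 'cnn' extra "
                "or use the handcrafted backend."
            ) from exc
        import torch
        model = torchvision.models.alexnet()
        state = torch.load(weights_path, map_location="cpu")
        model.load_state_dict(state)
        model.eval()
        self._torch = torch
        self._features = model.features  # ends at the third max-pool

    @property
    def n_features(self) -> int:
        return alexnet_pool5_dim()

    def encode(self, image: np.ndarray) -> np.ndarray:
        torch = self._torch
        img = np.asarray(image, dtype=np.float32)
        if img.max() > 1.0:
            img = img / 255.0
        x = torch.from_numpy(img)[None, None]
        x = torch.nn.functional.interpolate(
            x, size=(_ALEXNET_INPUT_SIZE, _ALEXNET_INPUT_SIZE),
            mode="bilinear", align_corners=False)
        x = x.repeat(1, 3, 1, 1)
        with torch.no_grad():
            act = self._features(x)
        return act.flatten().numpy().astype(float)


def get_backend(name: str, weights_path: str | Path | None = None):
    """Backend registry lookup: ``handcrafted`` or ``alexnet_pool5``."""
    if name in ("handcrafted", HandcraftedBackend.name):
        return HandcraftedBackend()
    if name in ("cnn", "alexnet_pool5"):
        return AlexNetPool5Backend(weights_path)
    raise ValueError(f"unknown feature backend {name!r}")


def extract_features(rois: list[RoiSample], backend) -> FeatureTable:
    """Code every ROI through ``backend`` into one aligned FeatureTable.

    Deterministic per backend: identical images give identical rows.
    """
    if not rois:
        n = getattr(backend, "n_features", 0)
        return FeatureTable(matrix=np.empty((0, n)), roi_index=[],
                            backend_name=backend.name,
                            feature_names=getattr(backend, "feature_names", None),
                            video_ids=[])
    rows = [backend.encode(roi.image) for roi in rois]
    return FeatureTable(
        matrix=np.vstack(rows),
        roi_index=[roi.roi_id for roi in rois],
        backend_name=backend.name,
        feature_names=getattr(backend, "feature_names", None),
        video_ids=[roi.video_id for roi in rois],
    )
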