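"""Unsupervised low-variance feature elimination.

CNN activations of mostly uniform gray crops contain many columns that barely
vary across the dataset (background-coding units); these carry no shape
information and are dropped before classification.  The filter is purely
unsupervised — it never sees class labels — and inside cross-validation it is
fitted on training rows only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import SelectionError
from .features import FeatureTable


@dataclass
class SelectionMask:
    """Boolean retain-mask over feature columns.

    ``threshold`` is the variance limit actually applied;
    ``reduction_factor`` is n_features / n_retained.
    """

    retained: np.ndarray            # bool vector over columns
    threshold: float
    backend_name: str = ""

    def __post_init__(self) -> None:
        self.retained = np.asarray(self.retained, dtype=bool)
        if self.retained.sum() < 1:
            raise SelectionError("a selection mask must retain at least one feature")

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    @property
    def reduction_factor(self) -> float:
        return self.retained.size / self.n_retained

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "threshold": self.threshold,
                "retained_indices": np.flatnonzero(self.retained).tolist(),
                "n_features": int(self.retained.size),
                "backend_name": self.backend_name,
            }, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionMask":
        with open(path) as fh:
            d = json.load(fh)
        retained = np.zeros(d["n_features"], dtype=bool)
        retained[d["retained_indices"]] = True
        return cls(retained=retained, threshold=d["threshold"],
                   backend_name=d.get("backend_name", ""))


def fit_low_variance_mask(features: FeatureTable, mode: str = "target_factor",
                          value: float = 50.0) -> SelectionMask:
    """Fit a retain-mask that drops features with small variation.

    Parameters
    ----------
    features
        Table whose per-column sample variances (denominator ``n - 1``,
        computed on raw unstandardized values) drive the selection.
    mode, value
        ``threshold``: retain columns with variance strictly greater than
        ``value``.  ``target_factor``: retain the ``ceil(n_features / value)``
        highest-variance columns (variance ties broken by keeping the lower
        column index), i.e. reduce the feature count by roughly that factor.

    Raises
    ------
    SelectionError
        For an all-constant matrix, fewer than 2 rows, or a mask that would
        retain nothing.
    """
    if features.n_rois < 2:
        raise SelectionError("need at least 2 rows to estimate variances")
    if mode == "threshold" and value < 0:
        raise SelectionError(f"variance threshold must be >= 0, got {value}")
    if mode == "target_factor" and value <= 0:
        raise SelectionError(f"reduction factor must be positive, got {value}")
    variances = features.matrix.var(axis=0, ddof=1)
    if np.max(variances) <= 0:
        raise SelectionError("all feature columns are constant; nothing to retain")

    if mode == "threshold":
        retained = variances > value
        threshold = float(value)
    elif mode == "target_factor":
        k = math.ceil(features.n_features / value)
        # stable top-k: sort by (-variance, column index)
        order = np.lexsort((np.arange(variances.size), -variances))
        retained = np.zeros(variances.size, dtype=bool)
        retained[order[:k]] = True
        threshold = float(variances[order[k - 1]])
    else:
        raise SelectionError(f"unknown selection mode {mode!r}")

    if not retained.any():
        raise SelectionError(
            f"threshold {value} eliminates every feature; lower it")
    return SelectionMask(retained=retained, threshold=threshold,
                         backend_name=features.backend_name)


def apply_mask(features: FeatureTable, mask: SelectionMask) -> FeatureTable:
    """Column-subset a FeatureTable; row order and alignment are unchanged."""
    if mask.retained.size != features.n_features:
        raise ValueError(
            f"mask length {mask.retained.size} does not match "
            f"{features.n_features} feature columns")
    names = features.feature_names
    if names is not None:
        names = [n for n, keep in zip(names, mask.retained) if keep]
    return FeatureTable(
        matrix=features.matrix[:, mask.retained],
        roi_index=list(features.roi_index),
        backend_name=features.backend_name,
        feature_names=names,
        video_ids=None if features.video_ids is None else list(features.video_ids),
    )
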