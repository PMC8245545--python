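"""Score-profile and confusion-matrix plots for run reports."""

from __future__ import annotations

import numpy as np
import pandas as pd

CLASS_COLORS = {0: "#6a3d9a", 1: "#e31a1c", 2: "#ff7f00", 3: "#1f78b4"}
CLASS_NAMES = {0: "healthy", 1: "SCD", 2: "THAL", 3: "HS"}


def plot_score_profile(profile: pd.DataFrame, ax=None):
    """Bar chart of per-video normalized scores, colored by assigned class.

    ``profile`` is the frame returned by :func:`erythroflow.decision.score_profile`:
    one row per video with the assigned class and its normalized score.  A
    stair line on a secondary axis shows the expected (truth) class.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3.2))
    x = np.arange(len(profile))
    colors = [CLASS_COLORS.get(int(c), "gray") for c in profile["assigned"]]
    ax.bar(x, profile["score"], color=colors, width=0.8)
    ax.set_xlabel("video index")
    ax.set_ylabel("normalized score")
    ax.set_ylim(0, 1.05)
    if profile["truth"].notna().all():
        ax2 = ax.twinx()
        ax2.step(x, profile["truth"], where="mid", color="black", lw=1.2)
        ax2.set_yticks(sorted(profile["truth"].unique()))
        ax2.set_yticklabels([CLASS_NAMES.get(int(c), str(c))
                             for c in sorted(profile["truth"].unique())])
        ax2.set_ylabel("expected class")
    handles = [plt.Rectangle((0, 0), 1, 1, color=CLASS_COLORS[c])
               for c in sorted(set(int(v) for v in profile["assigned"]))]
    labels = [CLASS_NAMES[c] for c in sorted(set(int(v) for v in profile["assigned"]))]
    ax.legend(handles, labels, loc="upper right", fontsize=8)
    return ax


def plot_confusion(confusion: np.ndarray, class_names: list[str] | None = None,
                   ax=None):
    """Annotated heatmap of a video-level confusion matrix."""
    import matplotlib.pyplot as plt

    confusion = np.asarray(confusion)
    if ax is None:
        _, ax = plt.subplots(figsize=(3.2, 3.0))
    k = confusion.shape[0]
    names = class_names or [CLASS_NAMES.get(i, str(i)) for i in range(k)]
    ax.imshow(confusion, cmap="Blues")
    for i in range(k):
        for j in range(k):
            ax.text(j, i, str(confusion[i, j]), ha="center", va="center",
                    color="black" if confusion[i, j] < confusion.max() / 2
                    else "white")
    ax.set_xticks(range(k), names, rotation=45)
    ax.set_yticks(range(k), names)
    ax.set_xlabel("decided")
    ax.set_ylabel("truth")
    return ax
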