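"""Synthetic slit-barrier flow videos with per-cell ground truth.

The generator emulates label-free brightfield recordings of red blood cells
(RBCs) flowing left-to-right through a microfluidic channel that contains a
vertical band of funnel-shaped micro-constrictions (the "slit barrier", a
mimic of the inter-endothelial slits of the spleen red pulp).  Every cell
elongates while squeezing through the slits; what differs between conditions
is what happens afterwards:

* ``healthy`` (normal) cells relax back to a near-circular projection within a
  short distance past the barrier;
* ``SCD`` (sickle cell disease) cells keep a strongly elongated projection;
* ``HS`` (hereditary spherocytosis) cells become smaller, rounder and
  higher-contrast spherocytes;
* ``THAL`` (thalassemia) cells show an irregular boundary with an internal
  dark inclusion (a Heinz-body-like precipitate).

Only a per-video fraction of a patient's cells is abnormal
(``abnormal_fraction``); even control samples carry a small baseline of aged,
poorly recovering cells.  Rendering is purely 2-D appearance — anti-aliased
deformed ellipses on a bright background with Gaussian noise and optional
per-frame defocus — because the downstream classifier consumes 2-D appearance
only; no membrane mechanics or hydrodynamics are simulated.

Every video is generated from an explicit integer seed and is byte-for-byte
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError
from .video_io import VideoRecord, write_video

CONDITIONS = ("healthy", "SCD", "THAL", "HS")
#: class labels used throughout: healthy 0, SCD 1, THAL 2, HS 3
CONDITION_LABELS = {"healthy": 0, "SCD": 1, "THAL": 2, "HS": 3}

#: eccentricity imposed on every cell while it squeezes through the slits
SLIT_ECCENTRICITY = 0.93
#: half-width (columns) of the rendered barrier band
BARRIER_HALF_WIDTH = 3

#: default fraction of abnormal cells per condition; controls carry a small
#: baseline of aged cells, patient samples are mixtures
DEFAULT_ABNORMAL_FRACTION = {"healthy": 0.05, "SCD": 0.8, "THAL": 0.8, "HS": 0.8}


@dataclass(frozen=True)
class ShapeModel:
    """Target post-barrier projection of one cell population.

    ``eccentricity`` is the relaxed target; ``relax_px`` the exponential
    relaxation length (px past the barrier); ``radius_scale``/``depth_scale``
    scale projected size and absorption contrast; ``irregularity`` adds a
    3-lobed boundary perturbation and ``inclusion`` a dark internal body.
    """

    eccentricity: float
    relax_px: float = 8.0
    radius_scale: float = 1.0
    depth_scale: float = 1.0
    irregularity: float = 0.0
    inclusion: bool = False


NORMAL_SHAPE = ShapeModel(eccentricity=0.15, relax_px=7.0)

ABNORMAL_SHAPES = {
    # aged/defective cells present even in controls: sluggish recovery
    "healthy": ShapeModel(eccentricity=0.75, relax_px=40.0),
    "SCD": ShapeModel(eccentricity=0.86, relax_px=6.0, depth_scale=1.15),
    "THAL": ShapeModel(eccentricity=0.55, relax_px=8.0, irregularity=0.22,
                       inclusion=True),
    "HS": ShapeModel(eccentricity=0.12, relax_px=6.0, radius_scale=0.68,
                     depth_scale=1.6),
}


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic video generator.

    Defaults mirror the acquisition regime of slit-barrier deformability
    assays: ~1000 frames per video at 85 fps, cells of ~8 px projected
    radius drifting a couple of pixels per frame.
    """

    frame_size: tuple[int, int] = (96, 384)   # (height, width) px
    n_frames: int = 1000
    fps: float = 85.0
    barrier_x: int | None = None              # default: mid-frame
    cell_radius_px: tuple[float, float] = (8.0, 0.7)   # mean, std
    n_cells: int = 40
    velocity_px_per_frame: tuple[float, float] = (2.0, 0.5)  # mean, std
    condition: str = "healthy"
    abnormal_fraction: float | None = None    # default per condition
    noise_sigma: float = 4.0                  # gray levels
    defocus_prob: float = 0.02                # per-frame blur probability
    background_level: float = 210.0           # gray level of empty field
    cell_depth: float = 90.0                  # absorption contrast, gray levels
    seed: int = 0

    def resolved_barrier_x(self) -> int:
        return self.frame_size[1] // 2 if self.barrier_x is None else int(self.barrier_x)

    def resolved_abnormal_fraction(self) -> float:
        if self.abnormal_fraction is None:
            return DEFAULT_ABNORMAL_FRACTION[self.condition]
        return float(self.abnormal_fraction)

    def validate(self) -> None:
        h, w = self.frame_size
        if h <= 0 or w <= 0 or self.n_frames < 0 or self.fps <= 0:
            raise ConfigurationError("frame_size, n_frames and fps must be positive")
        if self.condition not in CONDITIONS:
            raise ConfigurationError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        frac = self.resolved_abnormal_fraction()
        if not 0.0 <= frac <= 1.0:
            raise ConfigurationError(f"abnormal_fraction must be in [0,1], got {frac}")
        if self.n_cells < 0:
            raise ConfigurationError("n_cells must be non-negative")
        if self.cell_radius_px[0] <= 0 or self.noise_sigma < 0:
            raise ConfigurationError("cell_radius_px mean must be > 0, noise_sigma >= 0")
        bx = self.resolved_barrier_x()
        margin = 4 * self.cell_radius_px[0]
        if not (margin <= bx <= w - 1) or w < 2 * margin:
            raise ConfigurationError(
                f"frame width {w} too small for barrier at column {bx} plus "
                "pre/post regions")


@dataclass
class CellTruth:
    """Ground truth for one rendered cell."""

    cell_id: int
    shape_class: str          # "normal" | "abnormal"
    radius: float
    row: float
    x0: float                 # column at frame 0 (may be negative)
    velocity: float
    target_eccentricity: float
    relax_px: float


@dataclass
class GroundTruth:
    """Per-cell and per-frame ground truth of one synthetic video.

    ``positions`` has one row per (frame, cell) with the cell centre inside
    the frame, columns: frame, cell_id, row, col, eccentricity, semi_major,
    semi_minor, region (pre/slit/post), side (before/after), overlapped.
    Cells whose centre has left the frame are simply absent (exited).
    """

    condition: str
    label: int
    cells: list[CellTruth]
    positions: pd.DataFrame

    @property
    def n_abnormal(self) -> int:
        return sum(c.shape_class == "abnormal" for c in self.cells)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "condition": self.condition,
            "label": self.label,
            "cells": [asdict(c) for c in self.cells],
            "positions": self.positions.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            condition=payload["condition"],
            label=int(payload["label"]),
            cells=[CellTruth(**c) for c in payload["cells"]],
            positions=pd.DataFrame(payload["positions"]),
        )


def _eccentricity_at(col: float, barrier_x: int, pre_ecc: float,
                     target: ShapeModel) -> tuple[float, str]:
    """Projected eccentricity of a cell whose centre sits at ``col``.

    Pre-barrier the cell shows its own relaxed shape; inside the band it is
    squeezed to ``SLIT_ECCENTRICITY``; past the band the eccentricity relaxes
    exponentially from the slit value toward the cell's target with length
    ``target.relax_px``.
    """
    lo = barrier_x - BARRIER_HALF_WIDTH
    hi = barrier_x + BARRIER_HALF_WIDTH
    if col < lo:
        return pre_ecc, "pre"
    if col <= hi:
        return SLIT_ECCENTRICITY, "slit"
    d = col - hi
    e = target.eccentricity + (SLIT_ECCENTRICITY - target.eccentricity) * np.exp(
        -d / target.relax_px)
    return float(e), "post"


def _render_cell(frame: np.ndarray, row: float, col: float, radius: float,
                 ecc: float, shape: ShapeModel, depth: float,
                 region: str, phase: float) -> None:
    """Additively draw one anti-aliased cell into ``frame`` (float array).

    The cell is an area-preserving ellipse elongated along the flow (x) axis,
    darker than background with a slightly lighter centre (biconcave disc
    look).  THAL-style irregularity and inclusions are only applied outside
    the slit (the constriction dominates the shape inside).
    """
    r = radius * (shape.radius_scale if region != "slit" else 1.0)
    q = (1.0 - ecc ** 2) ** 0.25         # a = r/q, b = r*q  keeps area pi r^2
    a = r / q
    b = r * q
    irr = shape.irregularity if region == "post" else 0.0

    h, w = frame.shape
    pad = int(np.ceil(a * (1 + irr))) + 2
    r0 = max(int(np.floor(row)) - pad, 0)
    r1 = min(int(np.ceil(row)) + pad + 1, h)
    c0 = max(int(np.floor(col)) - pad, 0)
    c1 = min(int(np.ceil(col)) + pad + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = yy - row
    dx = xx - col
    rho = np.sqrt((dx / a) ** 2 + (dy / b) ** 2)
    if irr > 0.0:
        theta = np.arctan2(dy, dx)
        rho = rho / (1.0 + irr * np.sin(3.0 * theta + phase))
    alpha = np.clip((1.0 - rho) * b, 0.0, 1.0)       # ~1 px anti-aliased edge
    dip = depth * shape.depth_scale * (0.6 + 0.4 * np.clip(rho, 0, 1) ** 2)
    patch = alpha * dip
    if shape.inclusion and region == "post":
        rho_inc = np.sqrt(((dx - 0.25 * a) / (0.38 * b)) ** 2
                          + (dy / (0.38 * b)) ** 2)
        patch += np.clip((1.0 - rho_inc) * 0.38 * b, 0, 1) * depth * 0.8
    frame[r0:r1, c0:c1] -= patch


def _static_background(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Bright field plus the dark barrier band with periodic slit openings."""
    h, w = config.frame_size
    bg = np.full((h, w), config.background_level, dtype=float)
    bx = config.resolved_barrier_x()
    band = slice(max(bx - BARRIER_HALF_WIDTH, 0), min(bx + BARRIER_HALF_WIDTH + 1, w))
    pillar = np.full(h, 70.0)
    period = max(int(3.0 * config.cell_radius_px[0]), 6)
    open_w = max(period // 3, 2)
    for start in range(period // 2, h, period):  # slit openings
        pillar[start:start + open_w] = 165.0
    bg[:, band] = pillar[:, None]
    return bg


def generate_video(config: SyntheticConfig) -> tuple[VideoRecord, GroundTruth]:
    """Render one synthetic slit-barrier video plus its ground truth.

    Cells move left-to-right at constant per-cell velocity; each cell's
    barrier-crossing time is spread uniformly over the video so traffic is
    continuous.  Whether a cell is abnormal is an independent Bernoulli draw
    with probability ``abnormal_fraction``.  Overlapping cells (centre
    distance below the sum of radii) are allowed and flagged in the truth so
    detection tests can exclude them.

    Returns
    -------
    (VideoRecord, GroundTruth)
        Frames are uint8; the truth's per-frame positions are consistent with
        the rendered pixels.  Deterministic under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.frame_size
    bx = config.resolved_barrier_x()
    frac = config.resolved_abnormal_fraction()
    abnormal_model = ABNORMAL_SHAPES[config.condition]

    cells: list[CellTruth] = []
    for cid in range(config.n_cells):
        radius = max(float(rng.normal(*config.cell_radius_px)), 2.0)
        row = float(rng.uniform(radius + 2, h - radius - 3))
        velocity = max(float(rng.normal(*config.velocity_px_per_frame)), 0.4)
        # spread barrier-crossing times over the whole video
        t_cross = float(rng.uniform(0.05, 0.95)) * max(config.n_frames, 1)
        x0 = bx - velocity * t_cross
        abnormal = bool(rng.random() < frac)
        shape = abnormal_model if abnormal else NORMAL_SHAPE
        cells.append(CellTruth(
            cell_id=cid,
            shape_class="abnormal" if abnormal else "normal",
            radius=radius,
            row=row,
            x0=x0,
            velocity=velocity,
            target_eccentricity=shape.eccentricity,
            relax_px=shape.relax_px,
        ))
    phases = rng.uniform(0, 2 * np.pi, size=max(config.n_cells, 1))

    background = _static_background(config, rng)
    frames = np.empty((config.n_frames, h, w), dtype=np.uint8)
    rows: list[dict] = []
    pre_ecc = NORMAL_SHAPE.eccentricity

    for t in range(config.n_frames):
        canvas = background.copy()
        active: list[tuple[CellTruth, float, float, float, str]] = []
        for cell in cells:
            col = cell.x0 + cell.velocity * t
            if not (0 <= col < w):
                continue  # exited (or not yet entered)
            shape = (ABNORMAL_SHAPES[config.condition]
                     if cell.shape_class == "abnormal" else NORMAL_SHAPE)
            cell_pre = shape.eccentricity if cell.shape_class == "abnormal" else pre_ecc
            ecc, region = _eccentricity_at(col, bx, cell_pre, shape)
            active.append((cell, col, cell.row, ecc, region))
            _render_cell(canvas, cell.row, col, cell.radius, ecc, shape,
                         config.cell_depth, region, phases[cell.cell_id])
        # flag overlaps among active cells
        overlapped = [False] * len(active)
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                ci, cj = active[i], active[j]
                dist = np.hypot(ci[1] - cj[1], ci[2] - cj[2])
                if dist < (ci[0].radius + cj[0].radius):
                    overlapped[i] = overlapped[j] = True
        for k, (cell, col, row, ecc, region) in enumerate(active):
            q = (1.0 - ecc ** 2) ** 0.25
            r_eff = cell.radius * (1.0 if region == "slit" else
                                   (ABNORMAL_SHAPES[config.condition].radius_scale
                                    if cell.shape_class == "abnormal" else 1.0))
            rows.append({
                "frame": t, "cell_id": cell.cell_id, "row": row, "col": col,
                "eccentricity": ecc,
                "semi_major": r_eff / q, "semi_minor": r_eff * q,
                "region": region,
                "side": "after" if col > bx else "before",
                "overlapped": overlapped[k],
                "shape_class": cell.shape_class,
            })
        if config.noise_sigma > 0:
            canvas = canvas + rng.normal(0.0, config.noise_sigma, size=canvas.shape)
        if config.defocus_prob > 0 and rng.random() < config.defocus_prob:
            canvas = gaussian_filter(canvas, 1.5)
        frames[t] = np.clip(canvas, 0, 255).astype(np.uint8)

    positions = pd.DataFrame(
        rows, columns=["frame", "cell_id", "row", "col", "eccentricity",
                       "semi_major", "semi_minor", "region", "side",
                       "overlapped", "shape_class"])
    record = VideoRecord(
        frames=frames,
        video_id=f"synthetic_{config.condition}_{config.seed}",
        fps=config.fps,
        condition_label=config.condition,
        barrier_x=bx,
    )
    truth = GroundTruth(
        condition=config.condition,
        label=CONDITION_LABELS[config.condition],
        cells=cells,
        positions=positions,
    )
    return record, truth


def generate_cohort(
    n_videos_per_condition: dict[str, int],
    base_config: SyntheticConfig | None = None,
    seed: int = 0,
) -> list[tuple[VideoRecord, GroundTruth]]:
    """Generate a cohort of videos with per-condition counts.

    Per-video seeds are derived deterministically from ``seed`` via a
    :class:`numpy.random.SeedSequence`, so any cohort is reproducible and its
    videos mutually independent.  Video ids are ``{condition}_{i:02d}``.
    """
    base_config = base_config or SyntheticConfig()
    for cond, n in n_videos_per_condition.items():
        if cond not in CONDITIONS:
            raise ConfigurationError(f"unknown condition {cond!r}")
        if n < 0:
            raise ConfigurationError("video counts must be non-negative")
    total = sum(n_videos_per_condition.values())
    child_seeds = np.random.SeedSequence(seed).generate_state(max(total, 1)) % (2 ** 31)

    cohort: list[tuple[VideoRecord, GroundTruth]] = []
    k = 0
    for cond in CONDITIONS:
        for i in range(n_videos_per_condition.get(cond, 0)):
            cfg = replace(base_config, condition=cond, seed=int(child_seeds[k]))
            record, truth = generate_video(cfg)
            record.video_id = f"{cond}_{i:02d}"
            cohort.append((record, truth))
            k += 1
    return cohort


def strongly_separated_cohort(
    seed: int = 0,
    counts: dict[str, int] | None = None,
) -> tuple[list[tuple[VideoRecord, GroundTruth]], SyntheticConfig]:
    """A small cohort with large morphology margins for end-to-end checks.

    Disease videos contain only abnormal cells and controls a 2% baseline;
    cell traffic is sparse (few overlaps), noise is low and defocus off, so
    the class signal is limited by the pipeline, not by the rendering.
    Twelve videos by default (6 healthy, 2 SCD, 2 THAL, 2 HS).
    """
    counts = counts or {"healthy": 6, "SCD": 2, "THAL": 2, "HS": 2}
    base = SyntheticConfig(
        frame_size=(96, 224),
        n_frames=100,
        n_cells=10,
        cell_radius_px=(7.5, 0.5),
        velocity_px_per_frame=(2.2, 0.4),
        noise_sigma=3.0,
        defocus_prob=0.0,
    )
    cohort = []
    child_seeds = np.random.SeedSequence(seed).generate_state(
        max(sum(counts.values()), 1)) % (2 ** 31)
    k = 0
    for cond in CONDITIONS:
        frac = 0.02 if cond == "healthy" else 1.0
        for i in range(counts.get(cond, 0)):
            cfg = replace(base, condition=cond, abnormal_fraction=frac,
                          seed=int(child_seeds[k]))
            record, truth = generate_video(cfg)
            record.video_id = f"{cond}_{i:02d}"
            cohort.append((record, truth))
            k += 1
    return cohort, base


def write_cohort(cohort: list[tuple[VideoRecord, GroundTruth]],
                 out_dir: str | Path, fmt: str = "tiff") -> pd.DataFrame:
    """Persist a cohort (videos + truth JSON) and return/write its manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for record, truth in cohort:
        name = record.video_id + (".tif" if fmt == "tiff" else "")
        path = out_dir / name
        write_video(record, path)
        truth.to_json(out_dir / f"{record.video_id}.truth.json")
        entries.append({"video_id": record.video_id, "path": str(path),
                        "condition": record.condition_label})
    manifest = pd.DataFrame(entries, columns=["video_id", "path", "condition"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
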