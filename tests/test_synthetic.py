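"""Synthetic slit-barrier video generator: determinism, truth consistency."""

from dataclasses import replace

import numpy as np
import pytest
from skimage.measure import label as cc_label, regionprops

import erythroflow as ef
from erythroflow.synthetic import ABNORMAL_SHAPES, NORMAL_SHAPE

from conftest import TINY


def test_zero_cells_gives_pure_noise_and_empty_truth():
    cfg = replace(TINY, n_cells=0)
    video, truth = ef.generate_video(cfg)
    assert video.n_frames == cfg.n_frames
    assert len(truth.cells) == 0
    assert len(truth.positions) == 0
    # frames are background + noise only: no pixel darker than the barrier band
    non_band = np.delete(video.frames, np.s_[video.barrier_x - 3:video.barrier_x + 4],
                         axis=2)
    assert non_band.std() > 0  # noise present
    assert non_band.min() > 150  # no rendered cells


def test_same_seed_bit_identical_different_seed_differs():
    a1, _ = ef.generate_video(TINY)
    a2, _ = ef.generate_video(TINY)
    b, _ = ef.generate_video(replace(TINY, seed=TINY.seed + 1))
    assert np.array_equal(a1.frames, a2.frames)
    assert not np.array_equal(a1.frames, b.frames)


def test_abnormal_count_is_seeded_bernoulli_draw():
    cfg = ef.SyntheticConfig(frame_size=(64, 224), n_frames=1, n_cells=100,
                             condition="healthy", abnormal_fraction=0.05,
                             seed=123)
    _, truth = ef.generate_video(cfg)
    # frozen draw for this seed; close to the 5-cell expectation
    assert truth.n_abnormal == 4
    assert sum(c.shape_class == "abnormal" for c in truth.cells) == truth.n_abnormal


def test_every_rendered_cell_has_exactly_one_truth_record():
    _, truth = ef.generate_video(TINY)
    ids = [c.cell_id for c in truth.cells]
    assert len(ids) == len(set(ids)) == TINY.n_cells
    assert set(truth.positions["cell_id"]).issubset(set(ids))
    # recorded centres lie inside the frame (exited cells are absent)
    h, w = TINY.frame_size
    assert ((truth.positions["col"] >= 0) & (truth.positions["col"] < w)).all()
    assert ((truth.positions["row"] >= 0) & (truth.positions["row"] < h)).all()


def test_abnormal_shape_parameters_differ_from_normal_by_margin():
    """Class shape models are separated in parameter space: the elongating
    conditions by eccentricity, spherocytosis by size and contrast."""
    for cond in ("SCD", "THAL", "healthy"):
        margin = ABNORMAL_SHAPES[cond].eccentricity - NORMAL_SHAPE.eccentricity
        assert margin >= 0.3, cond
    hs = ABNORMAL_SHAPES["HS"]
    assert hs.radius_scale <= 0.8
    assert hs.depth_scale >= 1.3


def test_all_cells_elongated_inside_slit_band():
    _, truth = ef.generate_video(replace(TINY, condition="SCD",
                                         abnormal_fraction=0.5, seed=21))
    in_slit = truth.positions[truth.positions["region"] == "slit"]
    assert len(in_slit) > 0
    assert np.allclose(in_slit["eccentricity"], 0.93, atol=1e-9)


def test_measured_post_barrier_eccentricity_of_normal_cells(tiny_healthy):
    """Oracle on pixels: moments of thresholded masks around relaxed normal
    cells stay below the abnormal eccentricity regime."""
    video, truth = tiny_healthy
    pos = truth.positions
    sel = pos[(pos["region"] == "post") & ~pos["overlapped"]
              & (pos["col"] > video.barrier_x + 20)
              & (pos["col"] < video.frames.shape[2] - 10)]
    assert len(sel) >= 10
    measured = []
    for _, p in sel.iterrows():
        r, c = int(round(p["row"])), int(round(p["col"]))
        patch = video.frames[int(p["frame"]),
                             max(r - 12, 0):r + 12, max(c - 12, 0):c + 12]
        mask = patch < patch.mean() - 20
        labels = cc_label(mask)
        props = sorted(regionprops(labels), key=lambda q: -q.area)
        if props and props[0].area > 20:
            measured.append(props[0].eccentricity)
    assert len(measured) >= 5
    assert np.mean(measured) < 0.6  # below the elongated abnormal regime


def test_video_writer_reader_roundtrip_preserves_metadata(tmp_path, tiny_healthy):
    video, _ = tiny_healthy
    path = ef.write_video(video, tmp_path / "v.tif")
    back = ef.read_video(path)
    assert back.n_frames == video.n_frames
    assert back.fps == video.fps
    assert back.barrier_x == video.barrier_x
    assert np.array_equal(back.frames, video.frames)


def test_cohort_counts_and_reproducibility():
    base = replace(TINY, n_frames=4, n_cells=2)
    cohort = ef.generate_cohort({"healthy": 2, "HS": 1}, base, seed=9)
    assert [v.condition_label for v, _ in cohort] == ["healthy", "healthy", "HS"]
    assert [v.video_id for v, _ in cohort] == ["healthy_00", "healthy_01", "HS_00"]
    # per-video seeds differ, and regeneration is exact
    assert not np.array_equal(cohort[0][0].frames, cohort[1][0].frames)
    again = ef.generate_cohort({"healthy": 2, "HS": 1}, base, seed=9)
    for (v1, _), (v2, _) in zip(cohort, again):
        assert np.array_equal(v1.frames, v2.frames)
    assert ef.generate_cohort({}, base, seed=0) == []


@pytest.mark.parametrize("bad", [
    {"n_cells": -1},
    {"abnormal_fraction": 1.5},
    {"condition": "ANEMIA"},
    {"frame_size": (0, 100)},
    {"frame_size": (48, 40)},       # too narrow for barrier + regions
    {"fps": 0.0},
])
def test_invalid_configuration_rejected(bad):
    with pytest.raises(ef.ConfigurationError):
        ef.generate_video(replace(TINY, **bad))


def test_truth_json_roundtrip(tmp_path):
    _, truth = ef.generate_video(replace(TINY, n_frames=5))
    truth.to_json(tmp_path / "t.json")
    back = ef.GroundTruth.from_json(tmp_path / "t.json")
    assert back.condition == truth.condition
    assert back.label == truth.label
    assert len(back.cells) == len(truth.cells)
    assert len(back.positions) == len(truth.positions)
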