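"""Shared fixtures: tiny synthetic videos and one session-wide end-to-end run."""

from dataclasses import replace

import pytest

import erythroflow as ef
from erythroflow.pipeline import RunConfig, run_pipeline

#: small, fast generator configuration used across unit tests
TINY = ef.SyntheticConfig(
    frame_size=(48, 160),
    n_frames=30,
    n_cells=5,
    cell_radius_px=(7.0, 0.5),
    velocity_px_per_frame=(2.5, 0.4),
    noise_sigma=3.0,
    defocus_prob=0.0,
    seed=11,
)


@pytest.fixture(scope="session")
def tiny_healthy():
    """A 30-frame healthy-control video with all-normal cells plus its truth."""
    cfg = replace(TINY, condition="healthy", abnormal_fraction=0.0)
    return ef.generate_video(cfg)


@pytest.fixture(scope="session")
def tiny_rois(tiny_healthy):
    """Detections and after-barrier ROIs of the tiny healthy video."""
    video, truth = tiny_healthy
    detections = ef.detect_video(video, 5, 11, 0.35)
    rois = ef.extract_rois(video, detections, 32, barrier_x=video.barrier_x)
    return detections, rois


@pytest.fixture(scope="session")
def separable_run():
    """Full pipeline on the 12-video strongly separated cohort (two-class).

    Shared across the classification invariant and end-to-end acceptance
    tests; the run takes ~20 s and is executed once per session.
    """
    cohort, _ = ef.strongly_separated_cohort(seed=1)
    config = RunConfig(seed=1, problem="two_class", half_width=100,
                       keep_intermediates=False)
    report = run_pipeline(config, cohort=cohort)
    return report
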