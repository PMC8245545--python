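# Methods

This note documents the models, numerical choices and limitations behind
`erythroflow`, in the order data flows through the pipeline.

## The synthetic slit-barrier video model

The generator emulates label-free brightfield recordings of RBCs crossing a
vertical band of micro-constrictions.  It is an *appearance* model, not a
physical one: the downstream classifier consumes 2-D projections only, so
cells are rendered as anti-aliased, area-preserving ellipses (semi-axes
`a = r/(1-e²)^¼`, `b = r(1-e²)^¼` for eccentricity `e` and nominal radius
`r`) darker than the bright background, with a slightly lighter centre to
suggest the biconcave disc.  No membrane mechanics, hydrodynamics, pillar
matrices or 3-D motion are simulated.

Each cell moves left-to-right at a constant per-cell velocity drawn from a
normal distribution; barrier-crossing times are spread uniformly over the
video so traffic is continuous.  Shape follows position:

* **pre-barrier** — the cell's own relaxed shape;
* **inside the band** (±3 columns) — every cell is squeezed to eccentricity
  0.93, regardless of class: deformation in the slit is universal, only
  recovery differs;
* **post-barrier** — eccentricity relaxes exponentially with distance `d`
  past the band, `e(d) = e_target + (0.93 − e_target)·exp(−d/L)`, toward a
  per-population target.

Population shape targets (free design parameters — no quantitative
morphometry of patient cells is available to calibrate them, so they were
fixed once, before any end-to-end evaluation, at values that make the classes
visually distinct at the rendered scale):

| population | target e | L (px) | other |
|---|---|---|---|
| normal | 0.15 | 7 | — |
| aged (controls) | 0.75 | 40 | — |
| SCD abnormal | 0.86 | 6 | +15 % contrast |
| THAL abnormal | 0.55 | 8 | 3-lobed boundary irregularity, dark internal inclusion |
| HS abnormal | 0.12 | 6 | 0.68× radius, 1.6× contrast |

A single relaxation mechanism covers both behaviours of interest: normal
cells relax to near-circular within ~2 cell radii, SCD cells "relax" to a
shape almost as elongated as the slit imposes (so they effectively never
recover), and HS/THAL cells converge to their own non-circular stationary
projections.

Whether a cell is abnormal is an independent Bernoulli draw with probability
`abnormal_fraction` — patient samples are mixtures (transfusion therapy, mild
phenotypes), and even controls carry aged cells, so the per-condition
defaults are 0.8 for disease videos and a 0.05 baseline for controls.
Frames receive additive Gaussian noise (default σ = 4 gray levels on a
background of 210) and, with small probability per frame, a Gaussian defocus
blur.  Defaults mirror the acquisition regime of slit-barrier assays
(~1000 frames per video at 85 fps); tests and the acceptance run use
100-frame videos at the same geometry to keep runtimes in seconds.

All randomness flows from one integer seed per video; cohort generation
derives per-video seeds from a master seed through a `SeedSequence`, so any
cohort is byte-for-byte reproducible.

Ground truth records, per cell, its population parameters and, per frame,
the centre, rendered eccentricity, barrier side/region and an overlap flag
(centre distance below the sum of radii).  Overlaps are permitted — they
happen in real channels — and flagged so detection metrics can exclude them.

**The strongly separated preset** (`strongly_separated_cohort`) is the
cohort used for end-to-end checks: 12 videos (6 healthy, 2 per disease),
96×224 px frames, 10 cells per video (sparse traffic, few overlaps),
abnormal fraction 1.0 for disease videos and 0.02 for controls, σ = 3, no
defocus.  It is deliberately easier than patient data in every respect:
isolated, in-focus, rigidly parameterized cells with large morphology
margins.  Passing tests on it shows the pipeline is wired correctly and
that its decision logic behaves as designed — not that patient-level
accuracies would be reproduced on real recordings.

## Barrier location and cropping

The barrier is the darkest persistent vertical structure: the column-wise
mean over time (moving cells average out) is smoothed with a σ = 2 px
Gaussian and its minimum taken.  A dip is accepted only if it exceeds both
4 gray levels and 5 robust standard deviations (1.4826·MAD) of the profile,
otherwise estimation fails — a flat-field or noise-only video has no
barrier.  Cropping keeps `barrier_x ± half_width` columns; the default
half-width is 3 mean cell diameters, and windows reaching past the frame are
clipped with a warning rather than rejected.

## Detection and ROI stream

Canny edges (σ = 1.4) vote in a circular Hough accumulator over integer
radii `[r_min, r_max]` (default 5–11 px, i.e. the configured cell radius
±50 %); accumulator values are perimeter-normalized so a complete circle
scores ≈ 1.  Peaks below the sensitivity threshold (default 0.35) are
dropped and a greedy non-maximum suppression removes detections within
`r_min` px of a stronger one; ordering is by descending score with (row,
col) tie-breaks, so detection is fully deterministic.  Elongated in-slit
cells are weak responders by design; the analysis does not rely on them.

ROIs are fixed-size square crops (default 32 px) around each detection,
zero-padded at frame edges, tagged `after` iff the centre column strictly
exceeds `barrier_x`.  The default pipeline additionally drops ROIs scoring
below 0.40 and ROIs within 16 columns (~2 cell diameters) of the band:
the band vicinity is dominated by spurious edge responses from the
constriction structure and by cells that have not yet had room to relax, so
it carries no class signal.  These three values were chosen during pipeline
design by inspecting detection false-positive rates and score distributions
on synthetic videos.

Detection quality is measured against generator truth on positions that are
isolated (not overlap-flagged), outside the band, and quasi-circular
(rendered eccentricity ≤ 0.6) — the population the circular transform is
specified to find.  On the strongly separated preset, recall exceeds 0.95
with mean centre error below 1 px.

## Feature backends

The **handcrafted** backend computes, on the largest Otsu-foreground
connected component nearest the crop centre (cells are darker than
background; components under 5 px are treated as absent): area, perimeter,
circularity 4πA/P², eccentricity, solidity and the 7 Hu moment invariants;
plus mean/std/skewness of foreground intensity and a 6-bin radial intensity
profile of the whole crop.  A crop with no foreground yields a defined
all-zero shape block with whole-crop intensity statistics.  The descriptor
order is frozen under the backend name `handcrafted_v1` so stored feature
tables remain comparable.

The **alexnet_pool5** backend implements transfer-learning coding: the
grayscale crop is replicated to three channels, bilinearly resized to
224×224, scaled to [0, 1] and pushed through a frozen AlexNet feature
extractor; the flattened third max-pool activation (256·6·6 = 9216 values)
is the descriptor.  Weights must be a local file — the package never
downloads — and the backend raises a capability error pointing at the
handcrafted backend when torch or the weights are absent.  The
preprocessing choices (resize method, channel replication, no mean/std
normalization) are configuration frozen here, since nothing constrains them
externally.

Backends are interchangeable: swapping one changes the number of feature
columns, never the row alignment, and every downstream stage is
backend-agnostic.

## Feature selection

Columns whose sample variance (denominator n−1, computed on raw values —
the filter screens absolute variation, so no standardization precedes it)
falls below a limit are dropped.  Two modes: an explicit variance threshold,
or a target reduction factor that keeps the `ceil(n/factor)` highest-variance
columns (ties keep the lower column index).  The default factor is 50,
which takes the 9216-dimensional pool5 coding to 185 columns.  The filter is
unsupervised — it never sees labels — and inside LOEO it is refitted per
fold on training rows only; a leakage test perturbs the held-out video's
rows and asserts the fold's mask is unchanged.  Whether to fit it once
globally instead is exposed as an option, but per-fold is the leakage-safe
default.

## Classification and scores

Linear SVMs (squared-hinge, L2, C = 1 by default, deterministic primal
solver) on features standardized to zero mean/unit variance fitted on the
training rows — raw descriptor scales differ by orders of magnitude and a
linear SVM is scale-sensitive.  The four-class problem uses the native
one-vs-all decomposition (one separator per class, labels healthy 0, SCD 1,
THAL 2, HS 3).  Decision values map to normalized scores by a softmax
(binary margins become ±d/2 first), chosen because it requires no extra
calibration fit inside each fold, is monotone in the decision values, and
puts a boundary point at exactly (0.5, 0.5).  Per-ROI labels are the score
argmax with ties to the lowest class index.  Class imbalance is left
unweighted by default; inverse-frequency weighting is available and is what
the permutation-null test uses, since balanced weights remove the
leave-one-group-out artifact that otherwise drags a label-free null visibly
below 50 %.

LOEO holds out all ROIs of one video per fold (fold order = sorted video
ids).  Each ROI inherits its video's label, so per-ROI labels are noisy by
construction — that noise is the reason the video-level rules exist.  A fold
whose training partition is single-class is skipped with a warning and
recorded in the manifest, which also keeps per-fold training-row counts and
retained feature columns.  Cross-video correlation from the same subject is
not corrected: folds are per video, exactly as in the study design this
mirrors, and subject identity is not modelled at all.

## Cooperative decisions

Majority voting takes the modal ROI label; ties go to the larger per-class
score sum, then the lower class index (tie policy frozen here and covered by
tests, since nothing external specifies one).  The percentage-limit rule
(two-class only) flags a video unhealthy iff its unhealthy-ROI fraction
*strictly* exceeds the limit — "exceeds" is read as strict, and the boundary
case is tested.  Maximum trustiness sums each class's normalized scores over
the video; since per-ROI scores sum to one, the per-class sums total the ROI
count, and the winning sum divided by that count is reported as the video's
normalized score (the bar height in score-profile plots).  Efficiency is
defined as the trace of the video-level confusion matrix over the video
count, kept at full precision and displayed as an integer percentage.

Videos contributing no analysable ROI are flagged undecidable, excluded from
every matrix and listed in the run report; the report also carries a
per-condition count table whose internal identities (Control + RHHA = Total,
SCD + THAL + HS = RHHA) are recomputed and enforced on every run.

## Problem sizes and degenerate inputs

Unit tests run on 30-frame 48×160 px videos (seconds); end-to-end checks and
the acceptance script use the 12-video strongly separated preset
(~100 frames, ~4000 after-barrier ROIs, about 20 s per LOEO problem on one
CPU).  The study-scale fold arithmetic (79 videos, 3442 ROIs) runs on
randomly generated 5-column features, since the arithmetic is independent of
feature content.  Degenerate inputs are defined rather than fatal wherever a
definition exists: zero-cell videos render pure background, blank crops get
a zero shape block, empty prediction sets raise a decision error that marks
the video undecidable, all-constant feature matrices refuse selection.

## Known limitations

* The generator's class margins are design parameters, not measurements;
  synthetic accuracies say nothing quantitative about patient data.
* Rendered cells are rigid parametric shapes; real projections deform
  continuously, tumble and defocus in ways the defocus flag only gestures at.
* The circular Hough detector under-detects strongly elongated cells, so a
  disease video's ROI stream under-represents its most abnormal
  appearances; the decision rules tolerate this, but per-class ROI counts
  are biased.
* Subject-level aggregation (several videos per patient) is out of scope;
  decisions are per video.
* AVI input is read-supported but lossy; only TIFF/PNG round-trip exactly.
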