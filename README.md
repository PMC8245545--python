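# erythroflow

Video analysis for microfluidic red-blood-cell (RBC) deformability screening.

The spleen removes aged and defective red blood cells by forcing them through
micrometre-scale inter-endothelial slits; cells that cannot deform and then
recover their shape are retained.  Microfluidic chips mimic this filter with a
row of funnel-shaped micro-constrictions (a *slit barrier*) in a shallow
channel, and a brightfield camera records the cells flowing through it.  A
healthy RBC elongates inside a slit and relaxes back to a circular projection
shortly afterwards; cells from patients with rare hereditary hemolytic anemia
(RHHA) — sickle cell disease (SCD), thalassemia (THAL), hereditary
spherocytosis (HS) — keep elongated, irregular or spherocytic projections.

`erythroflow` turns such recordings into video-level diagnoses:

1. **Preprocess** — crop each frame stack to a window of columns around the
   barrier (located automatically from the temporal-mean intensity profile if
   not given).
2. **Detect** — localize quasi-circular cells per frame with a circular Hough
   transform on a Canny edge map; extract a fixed-size square ROI around each
   detection, tagged *before*/*after* the barrier.  No tracking: each cell
   contributes one ROI per frame it is seen in.
3. **Code** — map every after-barrier ROI to a descriptor vector through a
   pluggable backend: a deterministic handcrafted shape/intensity set
   (area, perimeter, circularity 4πA/P², eccentricity, solidity, Hu moments,
   foreground intensity statistics, radial profile), or the flattened
   third-max-pool ("pool5", 9216-dimensional) activation of a frozen
   pretrained AlexNet supplied as a local weights file (transfer learning; no
   fine-tuning, no downloads).
4. **Select** — unsupervised elimination of low-variance feature columns,
   either by a variance threshold or to a target reduction factor (default
   50), refitted inside every cross-validation fold.
5. **Classify** — linear SVMs for healthy (0) vs unhealthy (1) or the
   four-class problem healthy/SCD/THAL/HS (one-vs-all), evaluated
   leave-one-experiment-out (LOEO): each fold holds out all ROIs of one
   video.  Decision values become normalized per-class scores via a softmax.
6. **Decide** — aggregate a video's per-ROI predictions with one of three
   cooperative rules:
   * *majority voting* — the modal ROI label;
   * *unhealthy-percentage limit* — unhealthy iff the fraction of
     unhealthy-labelled ROIs strictly exceeds a limit (e.g. 30 %);
   * *maximum trustiness* — argmax over classes of the summed per-ROI scores.

   The video-level *efficiency* is the trace of the confusion matrix over the
   number of videos.

A synthetic video generator (`erythroflow.synthetic`) renders slit-barrier
scenes with per-cell ground truth — class-dependent post-barrier shape
dynamics, per-video mixtures of normal and abnormal cells, noise and defocus —
so the whole chain is testable without patient data.

## Worked example

```python
import erythroflow as ef
from erythroflow.pipeline import RunConfig, run_pipeline

cohort, _ = ef.strongly_separated_cohort(seed=1)   # 12 synthetic videos
report = run_pipeline(RunConfig(seed=1, problem="two_class",
                                half_width=100, keep_intermediates=False),
                      cohort=cohort)
maj = report["rules"]["majority"]
print(maj["confusion"], f'{maj["efficiency_percent"]}%')
print("per-ROI accuracy:", round(report["loeo"]["per_roi_accuracy"], 3))
```

prints

```
[[6, 0], [0, 6]] 100%
per-ROI accuracy: 0.914
```

All six healthy and all six disease videos are assigned correctly by majority
voting over their ROIs (confusion rows = truth, columns = decision), even
though ~9 % of individual ROI predictions are wrong — the cooperative rule
absorbs single-cell errors, which is the point of the method.  The same
report carries the 30 %/40 % percentage-limit and maximum-trustiness
matrices, the LOEO fold manifest, and per-condition ROI counts.

The CLI mirrors the pipeline stages
(`erythroflow simulate|preprocess|detect|extract|select|train-eval|decide|run-all`).

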