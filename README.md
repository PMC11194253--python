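# cvmgrowth

Staging mandibular growth from serial lateral cephalograms, and
classifying cervical-vertebrae crops by growth stage.

## The problem

Orthodontic treatment timing hinges on where a patient stands relative to
the pubertal mandibular growth spurt.  Serial cephalometric films let one
measure mandibular length directly — the Condylion-to-Pogonion (Co-Pog)
distance — and the growth *velocity* between consecutive films
(Δlength in mm / Δtime in months) identifies the spurt: each film is
labeled **pre-pubertal**, **pubertal**, or **post-pubertal** by whether
its preceding interval falls before, inside, or after the peak-velocity
window.  Those velocity-anchored labels then supervise an image
classifier that reads only the cervical-vertebrae region of the film, so
a single cephalogram can be staged without a film series.

This package implements that full pipeline as a tested library:

| module | role |
|---|---|
| `cvmgrowth.staging` | Co-Pog lengths, interval velocities, peak window, 3-stage labels, eligibility screen |
| `cvmgrowth.synthetic` | longitudinal growth-series generator (linear + logistic spurt) and stage-conditioned vertebral-column phantoms |
| `cvmgrowth.roi` | Basion-to-C4 crop, 64×64 resampling, per-crop min-max normalization |
| `cvmgrowth.datasets` | balanced selection, stratified 85/15 + 80/20 splits with a fixed per-class test count |
| `cvmgrowth.classifier` | seeded NumPy CNNs: a 3-conv/2-FC designed net and an 18-layer residual net, with rotation/shift/zoom augmentation and gradient-weighted class-activation maps |
| `cvmgrowth.evaluation` | per-class one-vs-rest sensitivity/specificity/PPV/NPV/accuracy with ranks, overall accuracy, Cohen's kappa (unweighted/linear/quadratic), Altman bands |

Real radiographs are not redistributable, so the synthetic module
generates growth series with a known spurt peak and vertebra-like
phantoms whose shape varies systematically with stage; every downstream
stage is exercised end to end on those.

## The statistics at the core

Growth velocity on the interval between films at ages $t_i < t_{i+1}$:

$$v_i = \frac{L(t_{i+1}) - L(t_i)}{t_{i+1} - t_i} \quad \text{(mm/month)},
\qquad L = \lVert \mathrm{Co} - \mathrm{Pog} \rVert .$$

Per-class one-vs-rest diagnostic measures from the 3×3 confusion matrix:
sensitivity $TP/(TP{+}FN)$, specificity $TN/(TN{+}FP)$, PPV
$TP/(TP{+}FP)$, NPV $TN/(TN{+}FN)$.  Agreement is Cohen's
$\kappa = (p_o - p_e)/(1 - p_e)$; with balanced true classes
$p_e = 1/3$ exactly, so $\kappa = (\mathrm{acc} - 1/3) \cdot 3/2$.
Kappa is interpreted on Altman's bands (≤0.20 poor … 0.61–0.80 good,
0.81–1.00 very good).

## Worked example

Recompute every evaluation-layer number recoverable from the published
per-class correct-detection counts (27/20/31 and 25/28/31 of 32 test
images per stage):

```bash
$ python analysis/05_published_metrics.py
designed_cnn: accuracy 0.8125, kappa 0.71875 (good)
  pre       sensitivity 0.84375
  pubertal  sensitivity 0.62500
  post      sensitivity 0.96875
residual18: accuracy 0.8750, kappa 0.81250 (very good)
  pre       sensitivity 0.78125
  pubertal  sensitivity 0.87500
  post      sensitivity 0.96875
```

Reading: of 96 held-out films (32 per stage), the designed network
identifies 78 correctly (accuracy 0.8125); since true classes are
balanced, chance agreement is exactly 1/3 and
κ = (0.8125 − 1/3)/(2/3) = 0.71875 — "good" agreement.  The residual
net's 84/96 gives accuracy 0.875 and κ = 0.8125 — "very good".

The numbered scripts under `analysis/` run the pipeline itself:
`01_simulate_cohort.py` (cohort + series manifest),
`02_stage_films.py` (velocity labels), `03_render_and_crop.py`
(phantoms + ROI crops), `04_train_classifier.py` (designed CNN at the
study's dataset geometry: 166/42/32 per class train/validation/test,
50 epochs), `05_published_metrics.py` (above).  A `cvmgrowth` console
script exposes the same stages
(`simulate`/`render`/`stage`/`crop`/`build-dataset`/`train`/`predict`/
`evaluate`/`heatmap`); every stage is byte-for-byte reproducible given
its `--seed`.

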