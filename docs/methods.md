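# Methods

## Growth model and staging rule

Mandibular length is the planar Euclidean Co-Pog distance in millimetres;
coordinates are accepted with an explicit mm-per-pixel scale (default
1.0, which is also what the synthetic generator declares).  Age
arithmetic is in months; fractional months are accepted on ingestion.

The synthetic growth law is a linear background plus a logistic spurt,

    L(t) = baseline + linear_rate * (t - 96) + spurt_gain * sigma((t - peak)/scale),

with sigma the logistic function and t in months.  Its velocity is a
logistic density: a single analytically known maximum at `peak_age_months`.
This is the simplest law with one velocity peak; the parameters and
their defaults are

| parameter | default | unit | meaning |
|---|---|---|---|
| baseline_length_mm | 100 | mm | mandibular length at age 8 |
| linear_rate_mm_per_month | 0.05 | mm/mo | background growth outside the spurt |
| spurt_gain_mm | 12 | mm | total extra length added by the spurt |
| peak_age_months | 144 | mo | spurt peak (subject priors: F 138±8, M 156±8, sex enters only here) |
| spurt_scale_months | 6 | mo | logistic time scale; interval-velocity peaks resolve when film gaps ≲ 4·scale |
| noise_sd_mm | 0 / 0.3 | mm | additive Gaussian length noise (0.3 in noisy studies) |

Film series carry 6–9 films, first age uniform in [96, 108] months,
consecutive gaps uniform in [9, 18] months — the eligibility window the
screen (`check_eligibility`) also enforces, together with the exclusion
of skeletal class III and syndromic cases.

Staging: per-interval velocity v_i = Δlength/Δmonths; the peak window is
the maximal contiguous run of intervals containing the (earliest) argmax
whose velocities are ≥ `relative_threshold` × max velocity.  The default
threshold 1.0 makes the window the argmax interval alone; smaller values
widen the pubertal class, which is how a roughly balanced three-class
dataset can be produced from real series.  Film i is labeled by the
position of interval i−1 relative to the window (before/inside/after →
pre/pubertal/post); the first film has no preceding interval and stays
UNLABELED — it is excluded from classifier datasets, the only reading
consistent with labels describing growth *prior to* a film.  Ties at the
maximum take the earliest qualifying run, making labeling deterministic.

A deliberate property of interval-averaged velocities: when the true
peak lies within ~2 months of a film boundary, the neighboring interval
can average higher and the recovered peak shifts by one interval.  The
package therefore defines staging ground truth at the velocity-sequence
level (the argmax of the noise-free interval velocities, which a
finite-difference oracle on L(t) reproduces exactly) and asserts
containment of the peak age only to within ±1 interval.

## Phantom renderer

`render_synthetic_roi` draws three stacked vertebral bodies (bright on
dark, 64×64) with two stage-dependent cues: the body height:width aspect
ratio (0.60 / 0.85 / 1.15 for pre/pubertal/post) and the lower-border
concavity as a fraction of body height (0.05 / 0.20 / 0.38), plus
Gaussian intensity noise (sd 0.05) and rotation jitter (±3°).  Both cue
sequences increase strictly with stage, so the classes are separable by
construction.

The cue spreads are chosen to survive the training augmentation family:
rotation, shift and ±10% zoom preserve aspect ratio and concavity
*fraction*, but a ±10% zoom scales absolute body heights by up to 1.22×
between extremes — adjacent-stage aspect ratios therefore differ by more
than that factor, and concavity steps are several pixels, so no
augmented view of one stage can alias another.  With narrower spreads
the designed network demonstrably stalls at two-of-three classes.

What the phantoms do not emulate: real radiographic texture, anatomy
beyond three bodies, projection geometry, exposure variation, or any
claim about which morphological features distinguish real stages.
Passing tests show the pipeline's machinery is correct and learnable
signal is recovered — not that real cephalograms reach any particular
accuracy.

## ROI extraction

The crop runs from the Basion row to the C4-inferior row (inclusive);
the horizontal window is centered on the landmarks' mean column with
half-width = `lateral_margin_frac` (default 0.5) × the vertical extent —
the superior/inferior limits are anatomically defined, the lateral
bounds are a design choice that keeps the column centered without extra
landmarks.  Resampling to 64×64 is bilinear (nearest-neighbour is
available and used as the order-preserving oracle in tests); intensity
is min-max rescaled per crop to [0, 1], with constant crops mapping to
all-zero by convention.  No smoothing, sharpening or histogram filtering
is applied.  Image coordinates are origin top-left, row index downward;
crop boxes are half-open internally and reported inclusive.  Crops with
fewer than 8 source rows are rejected as degenerate.

## Dataset construction

Balanced selection draws `n_per_class` images per stage (seeded, without
replacement; shortfalls take all and warn).  Splitting is stratified per
class: test = round(class_size × 0.15) — or a fixed per-class count
(default use: 32) that reproduces the reference 32/32/32 test row —
then validation = round(remaining × 0.20).  With class pools of
223/225/215 this rounding yields exactly 153/154/146 training and
38/39/37 validation images.  Splits are by image; a subject-grouped mode
(whole subjects per partition) exists but is off by default, matching
the reference protocol.  Caveat: image-level splitting lets films of one
subject span train and test, which inflates real-data accuracy
estimates; synthetic phantoms are independent draws, so the caveat does
not affect the tests here.

## Classifier and training

Two architectures, both single-channel 64×64 input, three output
classes, implemented in a small seeded NumPy layer stack (float32
compute, im2col convolutions over BLAS):

* **designed_cnn** — [3×3 conv → batch norm → ReLU → 2×2 max pool] ×3
  with channels (16, 32, 64), then flatten → dense(128) → ReLU →
  dropout(0.5) → dense(3) → softmax.  548,323 parameters.
* **residual18** — the standard 18-weighted-layer basic-block residual
  topology (3×3 stem, stages 64/128/256/512 of two blocks each, global
  average pool, dense), trained from random initial values with no
  frozen layers; **residual_small** is a two-block reduction for
  desk-scale experiments.

Training: seeded mini-batch Adam (initial rate 1e-3, the ecosystem
default), batch 32, cross-entropy loss; "decreasing learning rate" is a
×0.5 step decay every 50 epochs (configurable).  Augmentation draws per
image: rotation U(−20°, 20°), row/column shifts U(±10% of size), zoom
U(0.9, 1.1), applied as a single bilinear affine map with reflected
edges; zero-magnitude augmentation is exactly the identity.  The weights
of the best validation-accuracy epoch are retained.  Every source of
randomness (initialization, shuffling, dropout, augmentation) flows from
explicit integer seeds; two identical runs produce identical histories
and predictions.

Class-activation maps follow the gradient-weighted scheme: activations
of the last convolutional stage weighted by the spatial mean of the
predicted-class score gradient, rectified, max-normalized, and
upsampled to the input extent; an all-zero map is returned when nothing
activates (never a division by zero).

## Evaluation

The 3×3 confusion matrix (rows true, columns predicted, order
pre/pubertal/post) collapses per class to TP/FP/FN/TN; sensitivity,
specificity, PPV, NPV and per-class accuracy follow, each ranked across
classes (1 = best, ties share the better rank).  Zero-denominator
measures are reported as explicit undefined values, never as 0 or 1.
Cohen's kappa is computed in the disagreement form
κ = 1 − Σw·p_obs / Σw·p_exp for unweighted, linear and quadratic
weights; on balanced true classes the unweighted expected agreement is
exactly 1/3 regardless of predicted marginals, which is why the headline
kappas equal (accuracy − 1/3) × 3/2 and why the published values are
reproduced by the unweighted form even though the reference text says
"weighted".  Altman bands are upper-inclusive (≤0.20 poor, ≤0.40 fair,
≤0.60 moderate, ≤0.80 good, ≤1.00 very good).

When only per-class correct counts are known,
`matrix_from_correct_counts` rebuilds a balanced-truth matrix with
errors spread evenly over the wrong columns; overall accuracy, per-class
sensitivity and unweighted kappa depend only on the diagonal under
balanced truth, so any such completion reproduces them exactly.

## Problem sizes and numerical choices

Tests and the acceptance script run at these scales, chosen so the whole
suite completes comfortably on one CPU: staging checks over 200 seeded
series (plus 1,000-series and 1,000-matrix brute-force oracle sweeps at
1e-12 relative tolerance); the end-to-end experiment at 240 phantoms per
class (166/42/32 per class after splitting) for 50 epochs; unit-level
training checks on 30-per-class banks for 10 epochs.  Float32 network
compute is a deliberate speed/precision trade-off; all metric-layer
arithmetic is float64.  Degenerate inputs (empty classes, constant
crops, zero-activation maps, single-cell confusion matrices) raise typed
errors or documented conventions rather than silently returning numbers.

## Known limitations

* The phantom generator is a mechanistic stand-in; no statement about
  real-cephalogram accuracy follows from synthetic results.
* The peak-window threshold that would reproduce the reference study's
  near-balanced class sizes on real data is not recoverable from the
  published text; the default (argmax only) is the strictest reading.
* Image-level (not subject-level) splitting matches the reference
  protocol but is optimistic for real data; the grouped mode exists for
  honest real-data use.
* The residual net is validated structurally and for forward/gradient
  contracts at full depth, but large-scale training runs in the test
  suite use the designed network.
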