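# Methods

This note documents the models, parameters and numerical choices behind
`graspmvpa`, and what the synthetic validation does and does not establish.

## Synthetic data

**Design.** The default design mirrors a blocked delayed-action experiment:
three movement types (clockwise grasp, counterclockwise grasp, knuckle),
six blocks each, 72 trials per block — every block shows each of four
objects (2 shapes × 2 colors) 18 times in seed-reproducible random order.
Epochs span −100…1200 ms around object preview at 512 Hz; the sample count
is `floor(span × rate)` = 665, so five-sample feature windows give exactly
133 windows of ~9.8 ms. All counts, rates and windows are constructor
parameters; scaled-down variants used by tests change only sizes, never
logic.

**Noise.** Real EEG background is approximated by zero-mean Gaussian noise
with Gaussian-of-distance electrode correlation,
`(1 − ε)·exp(−(d/λ)²) + ε·I`, λ = 100 mm, sensor-noise fraction ε = 0.1.
This puts neighbor correlations at ~0.7–0.8 both before and after average
referencing — the operating point the < 0.6 bad-electrode rule assumes —
while distant electrodes decorrelate. An exponential decay was rejected:
its common mode is so large that average referencing pushes neighbor
correlations below 0.6, making the cleaning rule condemn perfectly good
channels. Optional 1/f temporal coloring is available (`temporal="pink"`);
the default is white, which is conservative for every test here. Reaction
times are truncated-normal (mean 286 ms, SD 72 ms, truncated at 0–1500 ms,
matching the behavioral summary the design emulates) and 4% of trials are
flagged invalid.

**Effects.** A ground-truth effect is a per-electrode topography (default: a
Gaussian scalp blob, FWHM 60 mm) times a Hann envelope inside one or more
windows, added to each trial with a sign given by that trial's label
(pillow/red/grasp/cw → +1). `reactivated` effects reuse one topography in
≥ 2 disjoint windows; `chained` effects use a distinct topography per
window; `sustained` effects occupy one contiguous window. `conjunction`
effects use an XOR code (sign = shape-sign × color-sign), visible to no
single-feature classifier. Carrier-band effects multiply the envelope by a
band-center cosine and use an on/off amplitude code instead of a polarity
code — band power is invariant to a pure sign flip, so a ±-coded
oscillation would be undetectable in power by construction. `amplitude` is
the pattern peak in units of the noise SD (a per-single-trial SNR);
pseudo-trial averaging over up to 18 epochs raises the effective SNR by
~√18.

**What the simulator omits.** No ocular or muscle artifacts, no forward
head model (topographies are abstract blobs, not dipole projections), no
continuous recordings, no trial-order or learning effects, and effect
latencies are locked to epoch time. Passing tests therefore establish that
the *analysis machinery* is correct and calibrated — not that real
recordings satisfy its assumptions.

## Preprocessing

Fixed order: bad-electrode detection → interpolation → average reference →
trial rejection. An electrode is bad when the *median* of its broadband
correlations with montage neighbors within 50 mm (computed over all epochs
concatenated) falls below 0.6; the median rather than the mean keeps one
dead channel from dragging its healthy neighbors below threshold. Bad
channels are replaced by inverse-distance-weighted averages of their good
neighbors (weights sum to 1) — spherical-spline interpolation would add
nothing for synthetic validation and the method is isolated behind one
function. Trials are rejected when flagged invalid or when the reaction
time leaves [100, 1000] ms; each rejection carries exactly one reason,
invalidity taking precedence. A zero-phase second-order Butterworth
0.1–40 Hz band-pass is available per epoch but off by default (the
simulator's output is already band-limited).

## Features

The ERP path is average → whiten → z-winsorize → window:

1. **Pseudo-trials.** All epochs of one object within one block are
   averaged, giving one trace per (block, object) — six traces per
   condition per action pool under the default design.
2. **Multivariate noise normalization.** The electrode covariance is
   estimated at every time point within each condition, averaged over time
   points and conditions into a single matrix Σ, shrunk by diagonal
   loading `Σ* = (1−λ)Σ + λ·(trΣ/p)·I` with λ = 0.05 (64 electrodes are
   estimated from few traces; without loading Σ is near-singular), and all
   traces are multiplied by the symmetric inverse square root Σ*^(−1/2).
   One common transform for all conditions.
3. **z + winsorize.** Each trace is standardized over its time × electrode
   values and clipped at ±3 SD, bounding outlier influence on the
   margin-based classifier while keeping the feature count fixed.
4. **Windows.** Consecutive non-overlapping groups of 5 samples,
   concatenated across electrodes (320 features at 64 electrodes); a final
   partial window is discarded. Windows start at the first epoch sample.

The spectral path prepends band power: two-way (forward–backward)
least-squares FIR band-pass at the canonical band edges, Hilbert analytic
signal, squared magnitude. Transition bandwidth is 1 Hz or 25% of the edge,
whichever is larger; the tap count targets three cycles of the low edge but
is capped below a third of the epoch length so that zero-phase filtering of
a single epoch is well-posed — this materially affects only delta, whose
filter on a 1.3 s epoch is consequently shallow. Power is not
log-transformed or baseline-normalized. Downstream grouping and
normalization are identical to the ERP path.

## Decoding

All contrasts use a linear soft-margin SVM (C = 1) on one window's
spatiotemporal features, with leave-one-pair-out cross-validation:
observations are paired across the two classes, each fold trains on all
remaining observations and tests on the held-out pair. Ties at decision
value exactly zero go to class 1. For balanced contrasts (shape, color)
pairs match on all other condition labels and block (24 pairs for grasping,
12 for knuckling under defaults). Orientation and action vary only between
blocks, so their pairs draw blocks at random (seed-controlled) within
matching object cells. The action contrast is imbalanced (48 grasp vs 24
knuckle observations): the minority class carries double misclassification
cost (2 : 1), majority-only pairs exist only for training, and every test
fold holds one observation of each class — 36 pairs, 35 training in every
fold.

Temporal generalization trains at every window and tests at every window
within the analysis range (default 0–500 ms); its diagonal reproduces the
time-resolved curve exactly under the same folds. The searchlight decodes
each electrode's ≤ 50-mm neighborhood on raw normalized samples within
100-ms bins.

The conjunction contrast targets one object (e.g., red pillow) against
observations sharing only its shape or only its color; the share-neither
object is excluded. Each minority observation is assigned one share-shape
and one share-color partner; a fold tests on (minority, one partner) and
drops the other partner from training as well, yielding 33/2 train/test
observations for grasping and 15/2 for knuckling. The four target
classifiers are averaged. The additive null model (README) is applied per
window and per searchlight cell; the exception rule operates on mapped
accuracies. **Caveat:** the additive model is the ceiling for *independently
combined* single-feature classifiers. When both single-feature codes are
near-saturated, a joint linear readout exceeds that ceiling with no
integrated representation present (the three classes become linearly
separable in the 2-D signal plane). Conjunction > additive is therefore
evidence of integration only away from saturation; the XOR recovery test
keeps its single-feature accuracies at chance for exactly this reason.

## Inference

**Cluster tests.** One-sample t statistics of (accuracy − chance) across
subjects, one-tailed. Point-wise thresholds are the 95th percentiles of the
per-point sign-flip permutation t distributions (10,000 flips by default;
the sign-flip ensemble reduces to one matrix product because flips preserve
per-point sums of squares). Clusters are maximal runs of supra-threshold
windows (or spatially connected electrode sets, per 100-ms bin, for
searchlight maps). Family-wise correction uses the permutation distribution
of the maximum cluster size, as a corrected p-value
`P(max null size ≥ observed) ≤ α`: with integer sizes the superficially
equivalent rule "size ≥ 95th percentile of max sizes" rejects at up to ~50%
whenever the null mass piles on the percentile value (measured: FWER 0.57
versus 0.025 for the corrected rule at 12 windows × 20 subjects).
Cluster mass is available as an alternative statistic only through the
cluster member lists; size is the default.

**ROI bootstrap.** The generalization plane is partitioned into a baseline
region (before information can plausibly exist), a diagonal band, symmetric
off-diagonal arms (early train × late test and transpose), and the
remaining triangular region. Full-scale defaults: baseline 0–50 ms ×
0–50 ms; diagonal |train − test| ≤ 30 ms within 100–500 ms; arms
140–210 ms × 270–500 ms plus transpose, excluding the diagonal band;
triangular the remaining off-diagonal cells; and an exploratory early-arms
variant anchored at 90–160 ms. These boundaries are configuration, not
constants: at the coarse window grids the tests use (≈ 20–39 ms windows)
the diagonal half-width widens to ~one window (45 ms), the arms test band
snaps to the window grid, and the baseline extends into the pre-stimulus
plane (−100…50 ms) so it contains enough cells for a stable reference.
Per ROI, each subject contributes the mean accuracy difference between the
two pools; bootstrap over subjects (10,000 draws) gives one-tailed 95%
intervals, and a region is significant when its mean difference exceeds the
baseline's and its 5th-percentile bound clears the baseline's
95th-percentile bound. `classify_dynamics` reads the pattern: triangular
significance → sustained (with or without arms), else arms → reactivated,
else diagonal → chained.

## Calibration and validation scales

Simulation-heavy checks run at reduced sizes chosen once for statistical
validity and tractability; logic and defaults are untouched.

- *Null calibration*: 200 cohorts × 20 subjects, 8 electrodes, 128 Hz,
  2 blocks per action, 2 repetitions per object, epochs −100…400 ms
  (12 windows), color/grasping decoding, 1,000 permutations per test. The
  family-wise false-positive rate must sit in the binomial 95% interval
  around 0.05 (the attainable level of the discrete max-size statistic at
  this window count is ≈ 0.03–0.04) and the grand mean accuracy within
  3 SE of 0.5 — the paired, label-symmetric CV scheme makes the null mean
  exactly ½ in expectation.
- *Dynamics recovery*: per dynamic, 20 cohorts × 8 subjects, 16 electrodes,
  3 blocks per action, epochs −100…520 ms, effect amplitude 3 (saturating),
  effect windows aligned to the feature-window grid; ≥ 18/20 cohorts must
  classify correctly. Bin alignment matters: effects bleeding partially
  into neighboring windows create weak spurious generalization cells that
  the triangular ROI picks up at saturating SNR.
- *Band specificity*: one beta-carrier color code; beta-power decoding
  must exceed 0.65 while delta-power decoding stays within 0.1 of chance.
- *Whitening benefit*: 20 simulations at amplitude 0.4; the mean paired
  accuracy difference (whitening vs covariance shrunk fully to the
  identity) must be non-negative. Full shrinkage (λ = 1) is the no-whitening
  control — the transform collapses to a global rescaling that the
  subsequent z-score removes.

## Known limitations

- Whitening delocalizes searchlight maps: the inverse-square-root transform
  mixes channels, so a focal source leaks weak decodable signal to distant
  neighborhoods (visible as small far-field searchlight accuracies).
- The noise normalization is fitted on all pseudo-trials before
  cross-validation, as in the procedure it implements; the folds audit the
  classifier, not the normalization.
- Sign-permutation inference needs enough subjects for a rich sign
  ensemble (2^n patterns); below ~10 subjects the discrete thresholds are
  coarse.
- The printed worked example of the conjunction mapping (p = 0.7 → 0.6)
  describes an idealized classifier; a finite-sample SVM undershoots the
  mapped value while still respecting the additive ceiling.
- The pairing rule for the action contrast is one reconstruction of an
  under-determined scheme; `make_cv_scheme` isolates it so alternatives can
  be swapped in.
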