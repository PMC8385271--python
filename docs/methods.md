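# Methods

This note documents the models, conventions and design choices behind
boldspect, in the spirit of a package methods appendix. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Signal model of the synthetic cohort

The generator (`boldspect.cohort`) emulates the statistical structure the
analysis assumes, not real anatomy. For subject *s*, voxel *v*, volume *t*
(time *t·TR*):

    y_svt = β_v(s) · r_t + A_sv · sin(2π f_sv t·TR + φ_sv) + ε_svt

* `r_t` — the task regressor: block boxcar (half-open blocks, sampled at
  acquisition times `t·TR`) convolved with a canonical double-gamma HRF
  (difference of gamma densities with shape parameters 6 and 16, undershoot
  ratio 6, 32-s support, peak normalized to 1; the positive lobe peaks near
  5 s, as in the SPM convention where "delay 6" names the shape parameter).
* `β_v(s)` — `effect_amplitude` (default 1.0, in units of the noise SD) at
  task and discriminative voxels of all subjects; discriminative voxels of
  group-1 subjects get `effect_amplitude + beta_shift`.
* The oscillation term exists only in group-1 discriminative voxels:
  amplitude `group_effect` (default 3.0), frequency uniform in `band_hz`
  (default 0.10–0.20 Hz, above the paradigm's harmonics at ~0.029·k Hz and
  below the 0.25 Hz Nyquist), phase uniform, both drawn per
  (subject, voxel).
* `ε` — stationary AR(1) noise, coefficient 0.3 (typical of BOLD at TR 2 s)
  and innovation SD `noise_sd` = 1.0. Motion regressors are Gaussian random
  walks (step SD 0.05) and are pure nuisance — they enter no signal.

**Why `beta_shift` exists.** A random-phase oscillation is mean-orthogonal
to the task regressor, so by itself it cannot move the GLM β and the
two-sample t selection stage would never find the planted voxels — yet a
pipeline of this design only works on cohorts where selection at the loose
|t| > 3 threshold *does* find voxels even though stricter tests find
nothing. We therefore couple a modest evoked-gain change to the oscillation
(`beta_shift = group_effect / 4` by default): physiologically, altered
neurovascular dynamics plausibly change both the oscillatory content and
the response gain. Setting `group_effect = 0` zeroes both, making the two
groups exactly exchangeable — the null configurations used in testing.

Block tables longer than the scan are truncated to `n_volumes` (the default
paradigm's six 35-s sessions would cover 105 volumes; the 60 acquired
volumes are authoritative). Discriminative voxels are grown as
face-connected clusters (default size 8) so the cluster-extent filter is
genuinely exercised.

Deliberately absent: anatomy and partial-volume structure, cardiac and
respiratory noise, scanner drift beyond what the AR(1) process produces,
motion-correlated signal. Passing tests therefore demonstrate correctness
of the machinery and recoverability of the planted effect class — not
performance on real scans.

## First-level GLM

Design: task regressor, the six motion columns (all-zero columns dropped
with a warning), DCT-II drift columns for every basis frequency
`k/(2·N·TR) < f_cutoff` (cutoff 1/128 Hz ⇒ exactly one drift column at
N = 60, TR = 2), and an intercept. Rank deficiency is an error naming the
collinear columns.

AR(1) handling: OLS residuals pooled over the analysis mask (voxels with
nonzero temporal variance) give a raw lag-1 autocorrelation; because OLS
residuals `e = M ε` understate the autocorrelation of `ε` — badly so when
the design contains slow regressors — the raw value is mapped back through
`E[e'Ae]/E[e'e] = tr(A·MΣ(ρ)M)/tr(MΣ(ρ)M)` tabulated on a ρ grid
(method-of-moments inversion; A is the symmetrised lag-1 operator). Both
sides of the regression are then prewhitened
(`x_t − ρ x_{t−1}`, first row scaled by √(1−ρ²)) and refit. A pooled ρ is
the default (stabler than voxelwise at 60 volumes); voxelwise estimation is
available (`pooled_ar=False`) and uses the same bias inversion per voxel.
Zero-variance voxels get β = 0 with a logged warning.

## Voxel selection

Group comparison is the pooled-variance two-sample t statistic
(group 1 − group 0, df = n₀ + n₁ − 2; zero-pooled-variance voxels get
t = 0). Selection thresholds |t| > 3 (two-sided by default so deficits are
eligible; a literal one-sided mode is available) and retains 26-connected
components **strictly larger** than `cluster_min = 5` voxels ("greater than
five" read strictly). Positive and negative excursions are labelled
separately so a cluster never mixes signs. Connectivity is configurable
(6/18/26). An empty selection raises a specific error; cross-validation
treats it as a failed fold rather than aborting.

## Spectrograms

Frames of `round(window_seconds/TR)` samples (10 s ⇒ 5), hop 1 sample,
tapered (periodic Hann by default; boxcar available), zero-padded to
`fft_length = 60` and transformed with an unscaled DFT; one-sided magnitude
by default. With 60 volumes this yields 31 bins × 56 frames — the only
hop/padding combination that produces that geometry from a 5-sample window,
which is why hop 1 and FFT length 60 are the defaults. Frequency axis
`k/(fft_length·TR)`; frame timestamps at window centres (metadata only).
Per-spectrogram min–max normalization to [0, 1] precedes classification
(standard for image-style inputs; z-score and none available). Constant
images normalize to all-zeros rather than dividing by zero.

Whether real pipelines of this family use magnitude, power or log-power is
generally unstated; magnitude is the default and power is one flag away.
The Parseval identity `Σ|X|² = fft_length · Σ|x_w|²` (boxcar window,
two-sided, per frame) and a direct DFT-summation oracle pin the convention
in the tests.

## CNN and baselines

Architecture: three blocks of (3×3 same-padded stride-1 convolution →
batch normalization → ReLU) with 16, 32, 64 channels — feature maps stay
31×56 throughout; no pooling — then flatten → FC-128 → ReLU → FC-2 →
softmax. Loss is binary cross-entropy on probabilities clipped to
[1e-7, 1 − 1e-7]. Training is mini-batch Adam (lr 1e-3, batch 32; epoch
count is per-study, see below), fully reproducible from the model seed and
shuffle seed; convolutions are im2col-equivalent shift-GEMMs and all
gradients are analytic, verified against central differences.

Batch-norm uses batch statistics during training and frozen statistics at
prediction. Because short training runs leave the exponential running
averages near their initialisation, the running statistics are re-estimated
with one pass over (a subsample of) the training set after the last epoch —
inference stays frozen-statistics, but the frozen values are meaningful.

Baselines: RBF-kernel SVM (C = 1.0) and L2 logistic regression (C = 1.0),
library defaults otherwise, on spectrograms flattened to 31·56 = 1736
vectors.

## Cross-validation, aggregation, permutations

Folds partition *subjects* (never spectrograms), stratified per group by
shuffling and round-robin dealing with staggered starts, so fold sizes
differ by ≤ 1 within each group and in total. Selection, classifier
training and normalization statistics involve training subjects only;
first-level βs and voxel spectrograms are label-free per-subject quantities
and are cached across folds and permutations.

Subject decision: `Pre = T/(T+F)`, threshold 0.5 with **ties assigned to
class 1** — this follows the decision rule's "otherwise" clause and biases
exact ties toward the patient class; it is deliberate and documented.

Permutation test: cohort labels are permuted (a within-training-split
variant is available behind a flag), the entire CV — selection included —
is re-run per permutation, and the null is the distribution of mean
subject-level accuracy; `p = (#{null ≥ Acc₀} + 1)/(n + 1)` (add-one, so
p > 0 always). A permutation in which no fold selects any voxel describes a
pipeline with no features, which classifies at chance: it enters the null
at 0.5 and is counted in `n_failed_permutations`. Under the strict default
thresholds this is the typical outcome for null cohorts — matching the
expectation that a correctly-behaving selection finds nothing when there is
nothing — so permutation calibration is tested with lenient thresholds
(|t| > 2.5, no size filter), where the chance-level property is
threshold-independent.

## Problem sizes and runtime choices

The full-scale study configuration (74 subjects, 10,000 permutations,
50-epoch training) is expressible in the config but not what the shipped
tests run. The tests use the sizes at which the guarantees are stated:
recovery runs with 20+20 subjects on a 16³ grid, 10-fold CV, CNN trained
2 epochs (the planted effect at 3× noise SD saturates well before that);
null calibration with 8+8 subjects on 8³ grids, 5-fold CV, and 99
permutations × 10 repetitions driven by the logistic-regression pipeline —
permutation calibration is a property of the permutation machinery, not of
the classifier inside it, and re-training a CNN ~10⁴ times serves no
inferential purpose. The permutation default in `RunConfig` is 200 for the
same reason (configurable up to any count).

## Numerical and degenerate-input conventions

* Boxcar sampling uses half-open blocks `[start, end)` at times `t·TR`.
* ρ estimates are clipped to [−0.95, 0.95]; noiseless fits are exact
  regardless of ρ because whitening is a bijective linear map.
* Softmax is computed with max-subtraction; probabilities are clipped only
  inside the loss.
* Cluster coordinates are reported 0-based, lexicographically sorted, and
  every TSV exporting them says so in its header comment.
* Single-class training sets, empty vote lists, empty selections,
  out-of-grid coordinates, unknown manifest labels and missing files all
  raise errors naming the offending subject/key.

## Known limitations

* The NumPy CNN targets this input geometry and small cohorts; it is not a
  general deep-learning stack (no GPU, no augmentation, no schedulers).
* Voxelwise AR(1) at 60 volumes is noisy even after bias correction; the
  pooled default trades spatial adaptivity for stability.
* The binomial bands used in the null tests treat subject-level decisions
  as independent; fold-shared training induces mild positive correlation,
  so those bands are approximate.
* Synthetic cohorts share one paradigm across subjects and contain no
  session or site structure.
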