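# Methods

## Scope and model

`tugfall` implements a fall-risk screening analysis for older adults built
around the Timed-Up-and-Go (TUG) test recorded with three wearable IMUs
(neck, right foot, left foot; tri-axial acceleration in G and angular
velocity in degree/s at 250 Hz, within ±16 G and ±2000 degree/s). The
ground truth throughout is the geriatrician's dichotomous fall-risk
assessment — faller (high risk, encoded 1) versus non-faller (0) — not
actual fall incidents, which enter only as an optional follow-up field.

Three predictors are compared under one evaluation protocol:

- a 1-D CNN on raw 3-channel signal windows (one modality × one location
  at a time),
- an RBF-SVM on nine per-subject summary statistics (mean, SD,
  coefficient of variation of each channel),
- the traditional clinical screen: TUG time dichotomized at 14 s.

## Synthetic cohorts

Real clinical recordings of this kind are not openly deposited, so the
simulator is a first-class, tested component and defines the package's
study conditions. Each subject's recording is a concatenation of five TUG
phases — sit-to-stand, walk out, turn, walk back, turn-and-sit — with
durations drawn per phase from per-class normal distributions (redrawn
while non-positive, at most 100 attempts). Waveform templates are
deliberately simple and class-discriminative rather than biomechanically
validated: raised-cosine step impulses on SI acceleration (AP harmonic,
pitch-rate burst) at the drawn cadence, with step intervals jittered at
the class's step-time CV; a mediolateral sway sinusoid at stride
frequency; half-sine yaw-rate lobes for turns; biphasic pitch-rate pulses
for the chair transfers. Feet receive alternating (left/right) step
bursts; the neck receives the superposition at half amplitude with full
sway, so location comparisons are meaningful. Gaussian sensor noise is
added (0.05 G, 4 degree/s) and signals are clipped to the sensor range.

Per-class defaults (chosen once as plausible geriatric-clinic values; the
source study reports no per-class kinematic effect sizes, so these are
free parameters of the package, not estimates of any real population):

| parameter | non-faller | faller |
|---|---|---|
| cadence (steps/s) | 1.9 ± 0.12 | 1.35 ± 0.12 |
| phase durations (s, mean) | 1.2, 3.2, 1.3, 3.2, 1.8 | 2.2, 5.5, 2.0, 5.5, 2.8 |
| total duration (s) | ≈ 10.7 ± 1.3 | ≈ 18.0 ± 2.5 |
| step-time CV | 0.03 | 0.09 |
| ML sway gain | 1.0 | 2.0 |

The duration distributions overlap (overlap coefficient ≈ 0.19), so a
duration threshold discriminates well but not perfectly — the tests
assert AUC strictly inside (0.5, 1) at n = 400. Consequences for
interpretation: passing tests show the pipeline recovers strong,
stationary class effects injected at known places; they say nothing about
effect sizes, sensor artefacts, walking aids, or non-stationary gait in
real cohorts.

## Preprocessing and segmentation

The curation chain is fixed: Fourier resampling of every channel from
250 Hz to 100 Hz (`scipy.signal.resample`; the implicit 50 Hz low-pass is
the intended band limit), then per-modality min-max mapping to [0, 1]
with signed extremes pooled over all samples, channels, locations and
subjects, then zero-padding every subject to the longest recording.
Pooling over *all* subjects reproduces the original protocol and leaks
test extremes into training; `scope="train_only"` is the statistically
sound alternative, in which case out-of-range transformed values are left
unclipped and logged. Signed extremes were chosen over magnitudes because
a magnitude range cannot map signed data onto [0, 1] invertibly.

Windows are 3 s with a 1 s stride (300 × 3 at 100 Hz); the count is
`floor((L − W)/S) + 1` and no partial trailing window is emitted (padding
guarantees coverage). A window is flagged padding-only iff its start lies
at or beyond the subject's true length; flagged windows are dropped by
default since they carry no subject information. SVM statistics are
computed per subject over the unpadded extent only (padding zeros would
corrupt the means), with population SD (ddof 0) and a CV guard: channels
with |mean| < 1e-8 get CV 0 plus a warning.

## The CNN

Layer sequence: [Conv(k=5, same) – BatchNorm – ReLU] × 2 – MaxPool(2) –
[Conv – BN – ReLU] × 2 – MaxPool(2) – Flatten – FC(1) – sigmoid, trained
with Adam (1e-3) on binary cross-entropy. Default filters (32, 32, 64,
64), batch 64, 30 epochs; all overridable. The network is implemented
directly in NumPy (im2col convolutions, standard BN backprop, argmax
pooling), which keeps training single-threaded and bit-reproducible given
the seed. The probability threshold is 0.5 with ties assigned to the
faller class — a screening test prefers sensitivity. The faller class is
1 and the output is P(faller) everywhere.

## Evaluation protocol

Subjects are split once, stratified 80/20 (per-class test count rounded
half up), strictly at the subject level; every iteration asserts the
train/test subject sets are disjoint. Each of the (default 100)
iterations resamples each set with replacement at `resample_factor`
(default 100) times its size; a subject drawn k times contributes its
windows k times. A fresh model is trained per iteration and evaluated on
the test windows (`eval_level="subject"` instead averages window
probabilities per drawn subject). Per-iteration seeds derive from the
master seed and iteration index, so results are independent of execution
order. Summaries are the mean and percentile (2.5/97.5) CI over
iterations; AUC inference reports the mean z of the per-iteration
Hanley–McNeil C-statistic tests next to the AUC-scale CI. An optional
`resplit_each_iter` redraws the 80/20 split every iteration; the fixed
split is the default, but the resplit mode is what makes shuffled-label
null checks meaningful, because a single frozen tiny test set pins the
chance-level AUC away from 0.5.

The traditional-TUG comparator needs no training: each iteration selects
10 fallers + 10 non-fallers without replacement, draws 2000 subjects with
replacement from those 20, classifies by TUG time ≥ 14 s and scores the
time itself for AUC.

## Clinical statistics

Cutoff rules are explicit about direction and boundary-inclusive on the
flagged side (TUG ≥ 14 s; 4-stage balance ≤ 30 s; ≤ 8 chair stands). AUC
is the rank-based Mann–Whitney statistic with ties counted ½; an
independent pair-enumeration oracle backs it in the tests. The Youden
sweep uses the sorted unique observed values as candidate cutoffs, ties
broken toward higher sensitivity then the lower cutoff. Odds ratios use
the cross-product with the Woolf log-SE CI; a single zero cell triggers
the Haldane–Anscombe 0.5 correction (flagged), two zero cells in a line
return NaN. Metrics with zero denominators are NaN, never silent zeros.

## Problem sizes

The default test suite and the acceptance script run scaled-down study
conditions chosen as the package's own sizing: cohorts of 10–60 subjects;
the flagship bagging-CNN run uses 40 subjects, 20 iterations, bootstrap
factor 2, filters (16, 16, 32, 32) and 6 epochs (a few minutes on one
CPU). The full-size protocol (98 subjects, 100 iterations, factor 100) is
available through the same configuration objects.

## Known limitations

- The simulator's gait templates are stylized; no walking aids, sensor
  clock drift, axis misalignment or gravity component are modelled.
- Cohort-wide normalization intentionally reproduces a train/test leak of
  the original protocol; use `train_only` scope for honest generalization
  estimates.
- The C-statistic's mean-z presentation mixes a test statistic with a
  percentile CI on the AUC scale; both ingredients are reported
  separately in the per-iteration table.
- Bagging CIs quantify resampling uncertainty around one split unless
  `resplit_each_iter` is set; neither mode is a substitute for external
  validation.
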