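# Methods

## Problem and scope

`harkit` implements the classic wearable-sensor activity-recognition
chain for the 12-activity protocol recorded with three body-worn
devices (chest, right wrist, left ankle) at 50 Hz: a unified session
data model with two serializations, sampling-rate adjustment,
fixed-duration windowing (batch and streaming), per-window time-domain
features, classifier training, and the two standard evaluation
protocols — offline repeated stratified k-fold cross-validation and
online, delay-aware scoring of a streamed recognizer.  A seeded
synthetic-data generator stands in for real recordings so the whole
chain is testable end to end.

## Data model

A `Session` is immutable metadata (subject, start/end, sampling rate,
device → sensor → axis tree) plus an ordered sample stream; every
channel shares one clock, and channel names are `device/sensor/axis`
paths.  Label coding: 0 is the null/transition class, 1–12 are the
activity codes (standing, sitting, lying, walking, stairs, waist bends,
arm elevation, knee bends, cycling, jogging, running, jumping).

The log dialect mirrors the public 12-activity benchmark release:
whitespace-delimited rows with 23 signal columns — chest acceleration
(x/y/z), 2-lead ECG, then ankle and wrist each acceleration, gyroscope
and magnetometer — and the integer label last.  That column order comes
from the released dataset's documentation, not from any single
authoritative spec, so the layout is a configurable `column_map`.  Logs
carry no time column; timestamps are synthesized as `i / rate`, and
clock regularity is checked to 1e-9 s.  Values are written with `repr`
precision, making the write→read round trip bit-exact.  The JSON
document stores the metadata block once at the top level (never per
sample) and renders with sorted keys, so parse→serialize is
byte-stable.

## Preprocessing

Downsampling is plain decimation (keep rows 0, k, 2k, …; rate / k) with
no anti-alias filter — the deterministic minimal choice, and the
recognition model itself applies no preprocessing.  Upsampling inserts
k−1 linearly interpolated rows per gap (length (N−1)·k+1, rate · k);
inserted rows copy the left neighbour's label.  Interpolation weights
are exactly zero at original grid points, so
`downsample(upsample(x, k), k) == x` bit-for-bit and affine sequences
are reproduced exactly on the finer grid.  Whether a deployed
implementation interpolates or repeats samples is a genuinely open
choice; interpolation is ours and is frozen here.

## Segmentation

Non-overlapping tiling with window length `n = floor(W · fs)` samples
(W = 2 s, fs = 50 Hz → n = 100 by default); a trailing partial window
is discarded, so Σ window lengths + tail = input length.  Each window
records its majority label, purity (majority fraction) and a transition
flag (purity < 1).  Majority ties break toward the first row's label,
falling back to the smallest code — deterministic by construction.  An
optional `stride` parameter exposes overlapping windows; the default
stride = n reproduces the study protocol.

The streaming segmenter buffers pushed rows and emits a window exactly
on the n-th, then resets; it is tested bitwise-equal to batch tiling.
A window-end prediction describes activity centred half a window
earlier; `segmentation_delay(W) = W/2` (1 s for the 2-s window) is a
separate, explicit operation so evaluation code cannot mis-align
silently.  Half-window centring is the only reading under which a 2-s
window produces a 1-s segmentation delay.

## Features

`window_statistic` fixes the formulas: mean Σx/N; sample variance
Σ(x−x̄)²/(N−1) (the common ML-toolkit convention; the source framework
names but never defines its statistics); std = √variance; max/min
element-wise; zcr = count of sign changes between consecutive samples,
where zeros inherit the most recent nonzero sign and leading zeros
count positive; mcr = zcr of the mean-centred signal.  Features are
computed per axis, not on magnitude signals.  The feature table is
channel-major (`channel:statistic` columns); every cell is tested
exactly equal to an independent scalar recomputation on the raw slice.

## Classification

Three kinds behind one surface: `zeror` (majority baseline, ties to the
smallest code), `gaussian_nb`, and `decision_tree` — a C4.5-style tree
(entropy splits, min leaf 2, optional cost-complexity pruning with
α = 1e-3, fixed seed).  Tree and naive-Bayes induction are delegated to
scikit-learn; what this module pins down is the contract: determinism
given (data, spec), class closure of predictions, feature-name checking,
and a versioned archive format for persistence (wrong format or version
is an explicit load error, never a silent deserialize).  With pruning
disabled the tree fits any consistent separable toy set perfectly, a
tested invariant.

## Evaluation

One-vs-rest per-class metrics from the K×K confusion matrix (rows =
actual): SE = TP/(TP+FN), SP = TN/(TN+FP), PPV = TP/(TP+FP),
NPV = TN/(TN+FN), F = 2·PPV·SE/(PPV+SE).  0/0 ratios are reported as
0.0 with an explicit degenerate flag.  Report rendering rounds to two
decimals; full precision is kept internally.

Repeated k-fold CV (default k = 10, stratified — the reference protocol
says only "ten-fold", stratification is our documented, switchable
default): repetition r shuffles with seed base + r, every window is
tested exactly once per repetition, and confusion counts are summed
over all folds and repetitions before metrics are derived once from the
aggregate — so the total equals repetitions × windows, and the report
is a single per-class table.  A class smaller than k under
stratification is an error that advises `stratified=False`.

Online evaluation scores a stream of `(end_time, label)` predictions
against per-sample truth: each prediction is compared with the truth
samples of its own window `[end_time − W, end_time)`; windows whose
truth is not unanimous, or that touch label 0, are transitions and are
excluded — the behaviour of a deployed recognizer without null-class
rejection.  With correct alignment, online scoring of a
batch-equivalent recognizer reproduces the offline confusion on the
same non-transition windows exactly (tested); shifting predictions by
+1 s without compensation strictly hurts (tested).

## Synthetic data generator

Real recordings of the protocol cannot ship with a library, so the
generator emulates their *structure*, not their waveforms.  Each
accelerometer channel is gravity plus an activity sinusoid plus
Gaussian noise:

    value(t) = g_axis + a·A_axis·sin(2π·c·f·t + φ) + N(0, σ)

with per-subject multipliers a ~ lognormal(0, 0.1) and
c ~ lognormal(0, 0.05) drawn once per subject from the root seed.
Design constants (declared, not estimated — per-activity amplitudes and
cadences of the real data are not published):

* static postures L1–L3: f = 0, distinct gravity orientations,
  σ = 0.25 m/s²;
* locomotion L4/L10/L11: shared waveform, cadences 1.5 / 2.5 / 2.9 Hz,
  amplitude ratios 1 : 1.7 : 1.96 (ankle-dominant, walking ankle
  amplitude 3.0 m/s²), σ = 0.40–0.55 m/s².  The 15% amplitude gap
  between jogging and running is comparable to the inter-subject
  amplitude spread, which makes them genuinely confusable — matching
  the hard-pair structure real studies report;
* bending pair L6/L8: shared 0.4–0.5 Hz chest-dominant sway with
  similar tilted chest gravity, the second confusable pair;
* stairs, arm elevation, cycling, jumping: device-specific signatures
  (e.g. cycling is ankle-dominant with a near-static chest).

Gyroscope and magnetometer channels carry consistent low-information
filler; the 2-lead ECG is a fixed quasi-periodic placeholder (~66 bpm)
so the full 23-channel dialect round-trips — neither is used for
recognition.  Null-label gaps of configurable length between activities
exercise transition exclusion online.  Determinism: a session is
bitwise reproducible from (profile, schedule, seed); the dataset
generator derives profiles and child seeds from one root seed.

What the generator does *not* emulate: harmonics and impacts of real
gait, sensor drift and saturation, orientation changes within an
activity, within-subject variability over time, and real ECG
morphology.  Passing tests therefore demonstrate that the pipeline is
correct and that its class geometry behaves as in the field
(near-diagonal confusion with locomotion errors dominating), not that
the specific accuracy figures transfer to real recordings — reproducing
published tables requires the released dataset and the original tree
configuration, which is unstated.

## Problem sizes and defaults

The standard experiment is 10 subjects × 12 activities × 30 s at 50 Hz
(18 000 samples/session, 180 windows/subject, 1 800 × 36 training
table), stratified 10-fold CV × 10 repetitions — the repetition count
is a deliberately scaled-down version of the reference protocol's 100,
which the CLI exposes via `--reps`.  The online experiment streams five
held-out subjects with 3-s null gaps.  The end-to-end run takes a few
seconds on one core; results quoted in the README were printed by
`scripts/acceptance.py` and the example scripts.

## Known limitations

* Non-integer resampling factors are unsupported (compose up∘down).
* The tree's hyperparameters are fixed defaults; no search is provided.
* Leave-one-subject-out CV and statistical model comparison are out of
  scope, as are visualization and device I/O.
* `extract_features` requires equal-length windows (the tiling
  segmenter guarantees this); ragged windows go through
  `window_statistic` directly.
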