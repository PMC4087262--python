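# Methods

This note documents the models and procedures implemented in `tfpbci`, the
defaults they use, and what the synthetic-data tests do and do not establish.

## Problem setting

Two-class motor-imagery decoding from multichannel EEG over sensorimotor
cortex. The paradigm is a long-trial protocol: each trial is a 10 s baseline,
a 2 s cue, a 10 s imagery (task) period and a 10–12 s rest, recorded from 21
electrodes at 1000 Hz. Decoding uses features of the mu (8–12 Hz) and beta
(18–25 Hz) rhythms extracted in a short window around task onset. The two
classes are imagery of hand-clench *speed* versus hand-clench *force*; the
package treats them as generic binary labels.

## Synthetic sessions

Real recordings for this paradigm are not publicly available, so the package
includes a generator whose output exercises every pipeline stage with known
ground truth.

Signal model, per channel:

```
x(t) = pink(t) + white(t) + Σ_r  g_r · E_r(t) · cos(θ_r(t))
```

* `pink`: 1/f-amplitude Gaussian noise, sd 6 µV; `white`: sd 2 µV.
* Each rhythm r (mu, beta) is an amplitude-modulated cosine. The envelope
  `E_r(t)` is the nominal amplitude (mu 6 µV, beta 3 µV) times a slow
  log-free modulation `clip(1 + 0.25·s(t))`, where `s` is unit-variance
  noise smoothed to a ~0.5 s correlation time. The instantaneous frequency
  drifts slowly around the band centre (mu: 10 ± 0.2 Hz, beta: 21 ± 0.8 Hz,
  clipped inside the band). Every channel carries an independent
  oscillator — own drift realization and own per-trial initial phase — so
  cross-channel covariance is generic rather than low-rank (a single shared
  oscillator would make each trial's rhythm rank-2 across channels and CSP
  could not generalize from such covariances). The per-channel gain
  `g_r ∈ [0.7, 1.3]` and a per-channel reference phase used by the
  phase-reset effect are fixed once per session. Slow modulations are
  synthesized at a 25 Hz internal rate and interpolated to the acquisition
  rate.
* Mu drift is deliberately slower than beta so that a phase reset at task
  onset stays coherent across the post-onset feature windows; with a large
  drift the accumulated phase `∫2π·f(t)dt` decorrelates across trials within
  half a second, and phase features carry no class information even when one
  is planted.

Class effects apply only during the task period (raised-cosine ramp,
0.2 s) on a configurable channel subset:

* `power_shift` – envelope multiplied by `effect_size` (an amplitude ratio;
  0.5 halves the amplitude, i.e. quarters band power, an ERD-like
  suppression). Trial-to-trial jitter: the multiplier is scaled by
  `exp(noise_sd·N(0,1))`.
* `envelope_shape` – a 1 Hz sinusoidal envelope modulation of depth
  `effect_size`, renormalized to preserve mean-square amplitude, so the
  envelope *trajectory* differs but mean band power does not.
* `phase_dynamics` – at task onset the rhythm phase is reset to
  `effect_size + N(0, noise_sd)` plus the channel's session-fixed offset.
  Preserving the per-channel offsets matters: resetting all channels to a
  common angle would synchronize neighbours and the surface Laplacian would
  then cancel the rhythm it is supposed to pass. Band power is untouched, so
  this effect is invisible to power/IA features by construction.

The generator is deterministic given its seed. What it does **not**
emulate: volume conduction and realistic cross-channel correlation
structure, eye/muscle artifacts, non-stationary drift across a session,
inter-subject variability, and the empirical relationship between imagery
content and rhythm dynamics. A green pipeline test therefore establishes
that the code recovers the class structure it was told to plant — not that
the planted structure is what real imagery produces.

## Preprocessing

1. Zero-phase Butterworth low-pass (order 4, run forward–backward) at
   125 Hz, then polyphase rational resampling to 250 Hz. Event indices are
   rescaled and rounded to the nearest output sample.
2. Broadband 5–45 Hz zero-phase band-pass.
3. Small surface Laplacian: each channel minus the mean of its montage
   neighbours (4-adjacency on the cap grid). Channels without neighbours
   pass through with a warning.
4. Per-rhythm band-pass (mu 8–12, beta 18–25 Hz) and epoching to
   [−1, +1] s around task onset. The feature range is only [−0.5, +0.5] s;
   the extra 0.5 s margin keeps filter and Hilbert edge transients out of
   the feature windows.

The filter family and order are not dictated by the problem; order-4
Butterworth run both ways was chosen for a flat passband and exactly zero
phase distortion, which matters for instantaneous-phase features. The
21-channel montage is approximated as a 3×7 grid (FC/C/CP rows); exact cap
coordinates are not needed anywhere downstream, only the neighbour relation.

## Features

For each band-limited channel, the discrete analytic signal
`z = x + i·H[x] = A·e^{iθ}` gives per-sample features

* band power `x(t)²`,
* instantaneous amplitude `A(t)`,
* instantaneous phase `θ(t) ∈ [−π, π]`,
* instantaneous frequency `dθ/dt / 2π` in Hz, computed on the unwrapped
  phase (jumps > π corrected by ±2π) with a central-difference gradient.

Each series is averaged in 0.5 s windows stepped by 0.125 s across
[−0.5, +0.5] s — five windows. Windows of power/IA/IF use the arithmetic
mean. IP uses the circular mean (angle of the mean unit phasor): the
arithmetic mean of wrapped angles is discontinuous at ±π and would turn a
tight phase cluster at ±π into a meaningless value near 0. The literal
arithmetic mean remains available (`ip_mean="arithmetic"`).

Columns are ordered feature-type-major, then channel, band, window:
21 channels × 2 bands × 5 windows = 210 columns per type, 840 for the
four-type combination. The eight supported feature sets are the four single
types and the combinations power-IP, IA-IP, IA-IP-IF, power-IA-IP-IF.

Min–max scaling maps each column to [−1, 1] via
`((v − min)/(max − min) − 0.5)·2`. In cross-validation the min/max are
always fitted on the training rows only — test rows may land slightly
outside [−1, 1]. Constant columns map to 0 with a warning.

## Feature selection

Relevance and redundancy use plug-in mutual information (bits) on
discretized columns: 8 equal-frequency bins for continuous features
(equal-width available), labels used as-is. The greedy criteria are

* MIFS: `J(X_k) = I(X_k;Y) − β·Σ_{j∈S} I(X_k;X_j)`, default β = 0.5
  (β is a judgment call in the literature; 0.5 is the conventional
  middle ground and is exposed as a parameter),
* mRMR: the same with β replaced by 1/|S|, keeping the penalty on the
  relevance scale as the selected set S grows.

Ties break toward the lowest column index, so rankings are reproducible.
The subset size is chosen by stratified inner cross-validation (default 5
folds) over nested prefixes of the ranking, taking the smallest size that
attains the maximum inner accuracy. The ranking length is capped
(default 64) to bound cost; the inner search can be thinned to every k-th
prefix (`k_step`).

The plug-in estimator is biased upward for small n (≈ (bins−1)(classes−1)/
(2n·ln2) per pair), but the bias is common to all columns and largely
cancels in the ranking.

## Classifiers

* **SVM** — soft-margin linear kernel, `min ½‖w‖² + C·Σξ`, default C = 1
  (deliberately not tuned), solved by scikit-learn's SVC with a tightened
  tolerance (1e−6) so the objective matches an independent QP solve to
  1e−3. Prediction is `sign(w·x + b)`.
* **ELM** — single hidden layer, default 100 sigmoid nodes. Input weights
  and biases are drawn uniformly from [−1, 1] from an explicit seed; output
  weights are `β = pinv(H)·T` with targets one-hot in {−1, +1}; prediction
  is the argmax output. With hidden count equal to the number of training
  samples and H full rank, training error is exactly zero.
* **CSP baseline** — trials band-passed 8–30 Hz, *without* the Laplacian:
  the 4-adjacency Laplacian matrix is (near-)singular, and the composite
  covariance of Laplacian-filtered data fails the rank check that `csp_fit`
  enforces before its generalized eigendecomposition. Per-trial covariances
  are trace-normalized and averaged per class; filters are the generalized
  eigenvectors of `(Σ₁, Σ₁+Σ₂)` at the extreme eigenvalues (two components
  by default, one from each end; eigenvalues pair as λ ↔ 1−λ under class
  swap). Trial features are `log(var_k / Σvar)` of the projected components
  (log-normalized variance is the stabilizing standard; raw variance is
  available), classified by SVM or ELM.

## Evaluation

`run_grid` evaluates every (regime, feature set, classifier) cell on
identical stratified 5-fold splits. Regimes: unscaled + MIFS, scaled +
MIFS, scaled + mRMR. Inside each training fold: fit scaling → rank → choose
subset size by inner CV → fit classifier; the test fold touches nothing but
the final score, and a dedicated test corrupts held-out rows to verify that
no fitted artifact changes. Cells report mean ± sd over folds; multi-session
results are pooled fold-wise (`merge_reports`), and the report states sd is
across folds of the pooled log.

Cell comparisons use a paired t-test on per-fold accuracies (Welch's
unpaired variant by flag), reporting the one-sided "A < B" indicator at
α = 0.01. Identical vectors give indicator 0 with a warning; a constant
non-zero paired difference has zero variance and is treated as a certain
ordering.

`export_topomap_values` produces the channels × classes table of mean
feature values in [0, 0.5] s — the data behind a scalp topography; no
rendering is included.

## Numerical and degenerate-input choices

* Epochs whose window would leave the recording are dropped and counted;
  an empty epoch set is an error.
* EDF output is 16-bit over a symmetric physical range taken from the
  signal extremes; the writer uses exactly the gain/offset mapping declared
  in the header, so round-trip error is bounded by range/2¹⁵. The true
  sample count is stored in the reserved header field because EDF pads to
  whole data records.
* Analytic-signal IF is unreliable on the first/last few samples
  (FFT-based Hilbert transform edge effects); the epoch margin keeps those
  out of all feature windows.
* Scaled-down session timing (1.5 s baseline, 0.5 s cue, 2 s task,
  0.5–0.7 s rest, often directly at 250 Hz) is used in tests to keep
  runtimes in CPU-minutes; generator defaults remain the full protocol.

## Known limitations

* The simulator's class effects are idealized single-mechanism injections;
  real imagery mixes power, envelope and phase changes with unknown
  relative strength, and published accuracies on real recordings cannot be
  reproduced from synthetic sessions.
* The MI estimator is the plug-in histogram estimate; no bias correction
  or k-NN estimator is provided.
* Binary classification only (the speed-vs-force contrast); the three
  intensity levels within each class are treated as within-class
  variability, not separate targets.
* CSP assumes exactly two classes and full-rank channel covariance.
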