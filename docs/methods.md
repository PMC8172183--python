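# Methods

## Problem and model

The pipeline classifies one-second EEG windows into four task conditions of
a TSST-style stress session — baseline rest, speech preparation, public
speech and mental arithmetic — from three spectral biomarkers and from
their autoencoder latent representations. The underlying physiological
model is the standard cognitive-load account: load raises frontal-midline
theta (4–7 Hz) and broadband gamma activity and suppresses the
parietal-midline alpha rhythm (7–13 Hz). The brain load index
`BLI = Theta(Fz)/Alpha(Pz)` and the relative gamma
`RG = AvPower(25–45 Hz)/AvPower(4–13 Hz)` are monotone read-outs of exactly
those shifts; the nine band-power features carry the same information
without forming ratios.

## Synthetic data generator

Real recordings for this protocol are not publicly available, so the
package ships a generator that produces the *study conditions* rather than
imitating any particular dataset. Each channel (Fz, Cz, Pz) is a sum of

* four band-limited Gaussian noise processes (theta 4–7, alpha 7–13,
  beta 13–39, gamma 25–45 Hz; 4th-order Butterworth band-passes applied
  forward-backward to white noise, normalised to unit RMS), scaled by
  per-band baseline RMS amplitudes of 4 / 6 / 3 / 1.5 µV — the usual
  resting scalp hierarchy with a dominant alpha — times a per-condition
  linear gain;
* 1/f pink noise (5 µV RMS, exponent 1) and white noise (1 µV RMS).

Total channel RMS lands at roughly 8–12 µV, inside the plausible 5–50 µV
scalp range. Session durations are 600 s baseline, 600 s preparation,
300 s speech, 300 s arithmetic at 250 Hz (optionally 1000 Hz to exercise
the resampling path).

Stress enters only through the gains: a condition with coupling `c` scales
the Fz theta gain and every channel's gamma gain by `(1 + c·s)` and the Pz
alpha gain by `1/(1 + c·s)`, with `s` the user-set stress strength and
couplings preparation 0.3 < arithmetic 0.6 < speech 1.0. Because expected
band power is the squared gain times the squared baseline RMS, the expected
BLI and RG of the four conditions are known in closed form and ordered
baseline < preparation < arithmetic < speech for every `s > 0`; `s = 0`
collapses all conditions to the same distribution (the null used by the
chance-level checks). No published effect size exists for these
between-condition spectral shifts, so `s` is a knob, with `s = 1` (a 2×
theta/gamma gain under speech) adopted as the default study condition.

Inter-subject variability is multiplicative log-normal gain jitter
(sd 0.1 on the log scale, one draw per subject shared across that subject's
conditions), which keeps powers positive. What the generator deliberately
omits: ocular/muscle artifacts, event-related potentials, non-stationarity
within a task, volume conduction and channel correlations. Passing tests
therefore demonstrate that the pipeline recovers spectral class structure
when it exists; they say nothing about robustness to artifacts or to the
session-to-session covariate shift that plagues real multi-condition EEG.

## Preprocessing

The "IIR filter" of EEG practice is realised as two cascaded 4th-order
Butterworth sections (1 Hz high-pass, then 50 Hz low-pass) applied with
`sosfiltfilt` for zero phase, the conventional EEGLAB-equivalent choice.
Resampling (polyphase) always follows filtering; at the target rate it is
the identity. Baseline correction is signal-domain: each task channel has
the mean of the corresponding baseline channel subtracted, and the baseline
recording is corrected by its own mean (a feature-domain variant would be a
trivial extension; the signal-domain reading is the literal one).
Windows are half-open `[start, end)` in 0-based window indices;
1-second non-overlapping windows, trailing remainder dropped.

Each task's window sequence is cut into three 200-window slices: thirds for
the 600-window tasks, and `[0,200)`, `[100,300)`, `[100,300)` for the
300-window tasks — the middle and final slices of a 5-minute task coincide
by construction (the source protocol's own figure defines them this way,
overriding a contradictory prose passage; the ranges are configurable).
Artifact-subspace reconstruction, ICA component rejection and dipole
fitting are out of scope: synthetic data is clean by construction. An
optional peak-amplitude window-rejection hook exists, off by default.

## Spectral estimation

Welch's method with 125-sample (0.5 s) Hann segments at 50% overlap:
2 Hz resolution, covering the 4 Hz band edge with at least three averaged
periodograms per window. Band powers integrate the PSD over band bins
(sum × bin width); `AvPower` in the RG is the *mean* PSD over band bins.
Both appear only inside ratios or as features later standardized, so the
convention only matters for cross-package comparison, and it is fixed and
documented here. Band intervals are half-open `[lo, hi)` so the shared
7 and 13 Hz edges count once; disjoint bands are exactly additive at the
bin level. The RG denominator is 4–13 Hz per the defining formula; a wider
4–23 Hz "slow rhythm" variant is selectable. A 2 µV, 10 Hz calibration
tone recovers its analytic `A²/2 = 2 µV²` alpha power to well within 10%.

## Autoencoder

Fully connected, input → 50–50–50 encoder (last layer is the code) →
mirrored 50–50 decoder → linear output of input width. ReLU hidden units
and a linear output are the standard pairing for real-valued
reconstruction under a squared-error-type loss; `tanh` and `identity` are
available (gradient checking uses `tanh` for smoothness). The loss is the
RMSE over all scalar entries; its gradient `(x′−x)/(N·L)` is singular at
zero residual and is defined as zero there. Training is plain minibatch
SGD — defaults lr 0.01, batch 32, max 200 epochs, patience 20 — with
Glorot-uniform initialisation from the run seed, full-dataset loss traced
every epoch, and best-epoch checkpointing (the returned weights are the
best seen, so the model never ends worse than it started). Inputs are
z-scored per column with statistics from the training data only; raw µV²
scales otherwise stall SGD. Latent codes are re-standardized before
classification (toggleable).

Two degenerate corners are implemented as specified and flagged here: the
1-dimensional BLI input still maps to a 50-unit code (a heavily
overcomplete representation whose value is empirical, not geometric), and
the nominal 100-unit input layer of the reference architecture cannot
equal the 9/3/1-dimensional feature sets, so the input width follows the
data and the 50-50-50 stack is kept.

## Benchmark protocol

Stratified 5-fold cross-validation over condition labels pooled across
subjects, seeded and deterministic. Per fold: standardization is fitted on
the training rows; for latent runs a fresh autoencoder is trained on the
training rows only (fold-safe; models are memoized per fold so several
classifiers share them). A global-autoencoder mode reproduces the
optimistic variant in which the representation sees all rows. Window-level
CV lets windows of one participant reach both folds and therefore inflates
accuracy relative to a new-subject setting; a subject-grouped CV mode is
provided for the conservative estimate. Group filters (`nurse` /
`control`) rerun any benchmark on one cohort arm.

Classifier defaults: RBF SVM (C = 1, inverse-variance kernel width);
AdaBoost with depth-1 decision-tree base learners and 50 rounds (a 10-round
variant is one config away, since both counts appear in the source
description); LDA and ridge at library defaults; random forest with 100
trees; k-NN with k = 5 and Minkowski p = 2. The deep-belief-network entry
has no published architecture; it is an optional adapter (two 64-unit
layers, no greedy pretraining) excluded from all acceptance checks. The
raw-amplitude control classifies decimated window samples directly and is
expected to sit near chance.

Chance-level assertions use 20 seeded label permutations and a ±0.05 band
around 0.25; above-chance assertions use an exact binomial test at
p < 0.01. Monotonicity of accuracy in stress strength is asserted
non-strictly over s ∈ {0, 0.5, 1, 2} at a fixed master seed.

## t-SNE diagnostics

Defaults: perplexity 10, 5000 iterations, learning rate 1000, seeded,
PCA initialisation (random for 1-D inputs, where PCA cannot supply two
components). "Perplexity 10%" in the source protocol is read as
perplexity = 10 — a percentage is not a valid perplexity — with a
`perplexity_frac` option for the literal 0.10·n reading. The learning rate
is tuned for cohort-scale inputs (hundreds to thousands of rows); on very
small inputs it over-fragments clusters, which is why the embedding tests
run at realistic n. Summary tables use the population (divide-by-n)
standard deviation.

## Problem sizes

The shipped checks run at desk scale, chosen once: 5 + 5 subjects for the
end-to-end cohort study (8 000 windows per feature set), 1 + 1 subjects for
the benchmark-shape run, 2 000 subsampled rows for the raw-amplitude
control and 1 000 for the permutation null. The printed headline accuracies
of the motivating study (83% raw-power SVM, 91% latent-power SVM) were
measured on 75 real participants whose recordings are not deposited
anywhere; they are not reproducible from synthetic data and are not
asserted. What is asserted instead is the full set of properties above:
formula-level oracles, spectral calibration, bookkeeping, gradient
validity, training sanity, above-chance signal recovery, monotonicity in
effect size, null behaviour and leakage guards.

## Known limitations

* Synthetic EEG has no artifacts and stationary within-condition spectra;
  accuracy figures on it do not transfer to real recordings.
* Window-level CV is the default to match the source bookkeeping, but it is
  optimistic; use `grouped=True` for subject-held-out estimates.
* The EDF writer emits plain EDF (16-bit), not EDF+; condition and group
  ride in the header identification fields and the CSV manifest.
* SGD on the RMSE loss is deliberately minimal (no momentum, no schedules);
  deep linear configurations converge slowly and may need more epochs than
  the defaults.
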