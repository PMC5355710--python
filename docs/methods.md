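# Methods

This note documents the models, the numerical choices, and the synthetic
data underlying `ctlmon`, in the order data flows through the package.

## Signal conditioning

**Low-pass filtering.** All channels pass a causal 3rd-order Butterworth
low-pass at 40 Hz (EMG rejection), implemented with second-order sections
(`scipy.signal.sosfilt`).  Causal filtering is used rather than zero-phase
because the monitor is meant to run online; the per-epoch band powers are
insensitive to the group delay.

**Ocular artifact removal.** The EOG channel drives an adaptive FIR
canceller of order M = 3 fitted by exponentially-weighted recursive least
squares with forgetting factor λ = 0.99.  The estimate v(k) = Σ_m h(m)
r(k+1−m) is subtracted from each EEG channel; the coefficients minimize
the exponentially forgotten squared error.  Initialization: h = 0,
inverse-correlation matrix P = I/δ with δ = 1e-3.  Because the regressor
(the EOG lags) is common to all EEG channels, one pass updates all eleven
channels with a shared gain vector.  When the reference is exactly silent
(u = 0) the update is skipped entirely, leaving coefficients *and* P
untouched; this both realizes the "silent reference ⇒ identity filter"
contract and avoids the unbounded P/λ growth a naive update would cause.
With λ = 1 the recursion converges to the batch ordinary-least-squares
solution (verified against a normal-equations oracle to 1e-6).

**Spectra and band powers.** Each non-overlapping 10-s epoch is analyzed
with a single rectangular-window periodogram — the only estimator that
realizes the nominal 0.1 Hz resolution on a 10-s segment (Welch averaging
would trade resolution for variance, changing the feature definition).
The spectrum is restricted to the 400 bins with centers 1.0–40.9 Hz.
Band powers are plain means of the bins whose centers fall inside
delta 1–4, theta 5–8, alpha 9–12, beta 13–32 and gamma 33–40 Hz.  The
delta band is nominally 0.5–4 Hz but the 0.1 Hz grid starts at 1 Hz, so
it is evaluated over the available 1–4 Hz bins.  On this grid the bands
do not overlap and no edge tie needs breaking.

**Heart rate.** R peaks are detected on the 5–15 Hz band-passed,
rectified ECG with an adaptive threshold at 0.6x the rolling maximum
(2-s window) and a 250 ms refractory period; the epoch's HR is the mean
of the instantaneous rates 60/RR.  Epochs with fewer than two detected
peaks yield a missing value that is forward-filled (backfilled at the
session start).  The detector is deliberately simple; it is adequate for
the high-SNR single-lead signals this pipeline expects and is not a
general-purpose QRS detector.

**Normalization.** Each of the 56 feature columns is z-scored over the
session (population s.d.).  Zero-variance columns are set to zero with a
warning rather than raising, since a flat HR column should not abort a
session.

## Performance and load classes

The three per-epoch indices are the mean fraction of the segment each
manual subsystem spends outside the error range (s_e) and outside the
transition zone (s_t), and the mean normalized set-point deviation
|d−c|/L (s_a).  The overall performance is
y = ½ min(s_e, s_t) + ½ (1 − s̃_a).  The normalization of s_a is not
prescribed beyond "normalized"; min–max scaling over the participant's
concatenated sessions, clipped to [0, 1], is used because it is the
weakest assumption that keeps y within [0, 1].

Classes 1–5 are cut from y at 1 − σ_o and 1 − z_i σ_o (half-open
intervals, the top interval closed at 1, class 5 the catch-all), with
σ_o the s.d. of y over the participant's concatenated sessions and
participant-specific coefficients z (tabulated defaults; participant A's
2.3/2.7/3.0 is the package default).  An optional quantile-matching
routine chooses z to approximate a target class-occupancy profile for
users without tabulated coefficients.

## Feature smoothing and reduction

The adaptive exponential smoother ε(k) = (1−g) ε(k−1) + g x(k) switches
g among g1 = 0.2 (innovation < a·σ), g2 = 0.1 (a·σ … b·σ) and g3 = 0.3
(≥ b·σ), with a = 1, b = 2.2 and σ the series s.d. estimated once on the
training session and frozen.  The update is written with the decay tied
to the selected gain — the convex form is the only reading under which a
constant series is a fixed point of the recursion, which we take as a
non-negotiable property of a smoother.  The intermediate band gets the
*smallest* gain: innovations of ambiguous size (plausibly motion
artifact) are trusted least, while very large jumps are tracked faster
as likely genuine level shifts.

Each EEG channel's five band-power series (after smoothing) is reduced
to one scalar x' = μᵀx by locality preserving projection: heat-kernel
weights exp(−d²/t) on a symmetrized 5-NN graph, t = median squared
pairwise distance, and μ the generalized eigenvector of
(XᵀLX, XᵀDX) with the smallest eigenvalue, unit-normalized.  Rank
deficiency (e.g. perfectly collinear band vectors) is handled by solving
in the non-null subspace of XᵀDX.  The sign of μ is fixed so the
training-set correlation of x' with performance is nonnegative, making
the salient features co-trend with y by convention.  The mapping is
fitted unsupervised on session 1 and frozen for session 2.  With the
smoothed HR this yields the 12-dimensional salient vector.

## NARX LSSVM classifier

Each LSSVM component solves the standard equality-constrained dual: the
(l+1)-dimensional saddle system with kernel matrix K + I/γ, γ = 100, and
the bias via the sum-to-zero constraint.  The RBF kernel uses σ² = 500.
A singular system is ridge-perturbed by 1e-10 with a warning.

The dynamic model combines complete component predictors (kernel
expansion plus own bias) with fixed convex weights — LSSVM1:
0.1·(RBF on the exogenous lag block) + 0.9·(linear kernel on the
autoregressive block); LSSVM2 adds 0.8·(local linear regressor) with the
first two weights at 0.02/0.18.  Putting the weights on whole
components, rather than on the biases alone, is the only identifiable
reading: multipliers trained independently per component carry no common
scale.  The local LSSVM2 term is refit at every step on exactly four
past samples (steps k−5…k−2; the window excluding k−1 is kept as
specified) whose inputs are lagged *measured* performance; whenever any
required lag precedes the series start the term is omitted and the
remaining weights renormalized to sum to one.

Training uses teacher forcing (measured y in the AR slots); test-time
prediction free-runs on the model's own outputs after a d2-step warm-up
seeded with measured values.  A series-parallel `predict_one_step` mode
(all AR slots measured) is also provided, which is the conventional
definition of one-step-ahead NARX prediction.

**Structure identification.** (d1, d2) minimizes
J = τ1 r_e + τ2 n_θ/n_θmax over the integer grid [1, 15]², τ = (0.8, 0.2),
with r_e the teacher-forced training RMSE.  Since the LSSVM multiplier
count depends on the sample count, not the orders, complexity is measured
by the regressor length n_θ = p·d1 + 2·d2 (p the exogenous dimension,
12 in the full pipeline), n_θmax at d1 = d2 = 15.  Ties are broken toward
smaller d1 + d2, then smaller d1, making the search deterministic.

**Evaluation.** Confusion matrices are laid out predicted x target;
per-class accuracy is column recall (undefined, reported as NaN, for
empty target classes).  The ordered classes induce four binary "cases":
in case m classes 1…m are negative and m+1…5 positive, with
FPR = FP/(FP+TN) and FNR = FN/(FN+TP).  The engine reproduces the
published worked-example tables exactly (overall accuracies 0.8500 and
0.8074 for the two documented participants' LSSVM2 runs; case-1
FPR/FNR 0.2429/0.0165 for the weaker variant).  Paired effect sizes use
Cohen's d = mean(Δ)/sd(Δ) with the sample s.d.  Naive-Bayes and KNN
(K = 30) reference classifiers are provided through scikit-learn for
comparison only.

## Closed-loop adaptive automation

A 90-step run (10 s per step) follows the six-block schedule
n = 1,3,4,4,3,1 (15 steps per block).  Each step draws an epoch record
(x', y) with replacement from the test session's bin for the current
task count (n = 2, absent from the sessions, maps to the n = 1 bin),
predicts ỹ with the LSSVM2 model (the drawn measured y feeds its local
term), and forms the error e = 1 − ỹ, clamped to [0, 1] since the
threshold laws are defined only for Ke ≥ 0.  The proportional+threshold
law removes 0/1/2 tasks for Ke in [0, 0.2)/[0.2, 0.8)/[0.8, 1] at every
step; the rule-based law uses the same thresholds but freezes n for the
two steps after any reallocation.  Both laws only move tasks toward the
machine (Δn ≥ 0), as specified; n is clamped to [1, 4].

At each block boundary n resets to the scheduled value and any hold is
cleared.  The reset is a deliberate design choice: with Δn ≥ 0 only, a
free-running n would sink to 1 within a few steps and stay there, which
contradicts both the published with-AA task-count averages (≈ 1.7–2.0
rather than ≈ 1) and the interpretation of the schedule as externally
imposed automation failures that re-impose load at each condition change.

Run i of a simulation uses child seed master+i; identical master seeds
give bit-identical trajectories.  Summaries n_MEAN, C_MEAN, y_MEAN
average over all steps of the (default 10) runs.

## Synthetic operators

`generate_session_features` emulates a participant at the salient-feature
level: performance y = clip(1.05 − 0.135·n(k) + AR(1) noise, 0, 1) with
AR coefficient 0.6 and marginal s.d. 0.05, and per-channel features
−(n(k) − n̄) + AR(1) noise whose variance is set analytically from a
target absolute correlation with y (defaults follow the published
participant-average pattern, ≈ 0.69–0.79 for the EEG channels and 0.32
for HR).  The base/slope values were chosen so that the two low-load
blocks sit in class 1, the n = 3 blocks in class 2, and the n = 4 blocks
straddle classes 3–5, giving every class at least 2% occupancy — a
full-rank confusion matrix — while keeping the load-performance
correlation near the ceiling the correlation targets assume.

`generate_raw_recording` builds the 13-channel raw signal: per-band
band-limited Gaussian carriers with load-modulated amplitudes (theta up,
alpha down with load by default), a Hanning-pulse blink train on the EOG
(12/min) leaking into the frontal channels, and an R-wave pulse train
whose rate rises 8 beats/min per extra manual task, plus white sensor
noise.  `generate_narx_process` provides a linear NARX oracle with known
orders — default (2, 4) with coefficients (0.5, 0.4) and
(0.3, 0.1, 0.05, 0.35), stable by construction — for structure-recovery
and prediction tests.

What the synthetic data does *not* emulate: volume-conduction structure
across channels, non-stationary drift between sessions beyond seed
changes, EMG residue above 40 Hz, operator adaptation transients at
control-mode switches, or realistic ECG morphology.  Tests passing on
these data therefore validate the pipeline's mechanics and the method's
comparative claims (e.g. measured-feedback LSSVM2 beating LSSVM1, AA
improving mean performance), not field performance on human recordings.

## Problem sizes and defaults

Sessions are 540 epochs (6 blocks x 90); simulations 90 steps x 10 runs;
structure searches on the full [1, 15]² grid use series of length 300
(oracle process) — chosen so each such search solves 450 small dual
systems, which completes in roughly a second.  The acceptance script's
synthetic study uses the same sizes as the worked example in the README.

## Known limitations

* The RLS canceller assumes the EOG channel is itself EEG-free; real
  EOG electrodes pick up frontal EEG, which this model ignores.
* LSSVM2 requires measured performance through k−1 at prediction time;
  where it is unavailable the model silently degrades to its first two
  terms (renormalized), which is closer to LSSVM1 behavior.
* The controllers never hand tasks back to the operator; sustained
  over-aiding is out of scope, as is detection of risky states caused by
  inappropriate aiding.
* Structure selection optimizes training fit plus a complexity penalty,
  not cross-validated error; with very short series it can under-select
  the exogenous order by one.
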