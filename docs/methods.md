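# Methods

This note records the models, parameter choices and numerical conventions
behind `prederr`, and what the synthetic data do and do not establish.

## Task simulator

A session is 35 training trials (5 intro, 15 easy-staircase, 15
hard-staircase) followed by eight 75-trial blocks, four easy and four hard
in seeded random order. A trial is won when |RT − 1 s| ≤ t/1000 for the
tolerance t (ms) in force. Staircase steps are −3/+12 ms (easy) and
−12/+3 ms (hard) after wins/losses, clamped to [15, 400] ms. Neutral
feedback replaces the outcome on an i.i.d. 12 % of main trials and, by
default, does not drive the staircase (feedback-driven titration; a config
switch updates on the hidden outcome instead). Inter-trial intervals are
drawn from {0.7, 1.0} s. Training starts wide (easy 300 ms, hard 100 ms).

**Staircase bookkeeping.** Over any stretch of staircased trials,
accuracy = equilibrium − Δt/(15·n) + truncation/(15·n), where equilibrium
is 12/15 (easy) or 3/15 (hard), Δt is the net tolerance change and
truncation collects steps clipped at the bounds (always inflating
accuracy). Hence any *stationary* agent with continuous staircases clamps
at or slightly above 80 %/20 %. Group accuracies of ~83 % easy and ~18 %
hard — easy above, hard below equilibrium — require (i) per-block
re-initialization of each staircase to its training-calibrated level, so
easy blocks repeatedly start above equilibrium and descend at the slow
−3 ms step while hard blocks start below a drifting equilibrium and climb
at the slow +3 ms step, and (ii) time-on-task deterioration. Per-block
re-initialization is therefore the default (`staircase_continuous=False`);
we read the training's stated purpose — initializing both staircases to
individual performance levels — as defining each block's starting point.

**Agent model.** RTs are Gaussian around 1 s. Per participant: timing SD ~
U(0.08, 0.15) s (typical human Weber fractions for a 1 s interval), a
linear time-on-task slowing of the mean ~ N(5·10⁻⁴, 1·10⁻⁴) s per trial, a
fractional SD growth of 4·10⁻⁴ per trial, and a 2 % lapse rate (uniform
RTs on [0.6, 1.4] s). No trial-level learning is modeled. The
deterioration magnitudes were calibrated once, before any analysis code
existed, so that the simulated staircase dynamics land in the reported
accuracy regime (≈83 %/18 % with the 0.6–1.4 s RT screen applied, with
between-participant SDs of ~2 points); they are larger than a fresh
observer would show but consistent with hour-long vigilance decrements.
Block accuracies are computed over non-neutral main trials retained by the
RT screen, matching how analyzed trial sets are defined downstream.

**Oddball task.** 10 training + 3×130 main trials; conditions drawn i.i.d.
with P(standard, target, novel) = (0.755, 0.1225, 0.1225); Gaussian button
RTs (0.364 ± 0.063 s) on targets only.

**Subjective ratings.** On every third main trial the agent reports its
true analytic win probability plus a difficulty-specific bias (defaults
−0.10 easy / +0.10 hard) and Gaussian noise, clipped to [0, 1], before
feedback. Bias recovery compares ratings to model-based probabilities per
participant and difficulty; clipping slightly shrinks recovered biases
near the scale ends.

## Behavioral model

The logistic win model is fit per participant by ML on non-training,
non-neutral trials, with tolerance in **milliseconds** (so β₁ is log-odds
per ms). Predictors enter regressions in raw units (no centering or
scaling), so coefficients read as amplitude per feature unit. Outcome
probability is each participant's observed outcome-class frequency within
difficulty over non-training trials. Neutral trials are excluded from the
fit but receive EV/RPE features from their tolerance. Control
expected-value variants replace single-trial p_win with block accuracy or
a trailing 5/10-trial accuracy (causal window, truncated at block starts so
trial alignment with epochs is preserved). VIF is computed within the full
predictor set (the default; a pairwise check is a two-column call).

## EEG synthesizer

Each component is a Gaussian-windowed cosine with envelope FWHM of two
cycles, an isotropic Gaussian topography (width 0.4 head radii on the 2D
BioSemi-64 layout, weight exactly 1 at the peak channel) and single-trial
amplitude polarity·(intercept + slope·feature), gated by a condition mask.
Defaults: FRN (6 Hz, 216 ms, Fz, −, slope 5 µV per RPE-magnitude unit,
negative outcomes = easy loss, easy neutral, hard loss), RewP (3 Hz,
310 ms, Pz, +, slope 5, positive outcomes = easy win, hard win, hard
neutral), and a late frontal probability component (4 Hz, 380 ms, FCz,
amplitude 6 − 6·probability µV, all trials). With 1/f noise of 10 µV RMS
(exponent 1, spectrally shaped white noise per trial and channel,
spatially uncorrelated) plus 2 µV white noise, single-trial component SNR
at the peak is ≈0.5: group effects are detectable at desk scale but not
trivial. Per-participant DC offsets (SD 1 µV) exercise the random
intercept on raw epochs; baseline correction removes them, so analyses of
preprocessed data sit near the zero-variance boundary unless per-
participant amplitude factors (log-SD option, shared across tasks for the
Oddball correlations) are enabled. Epochs are −0.2 to 1.0 s at 250 Hz
(301 samples), float32, HDF5-serialized with their trial table.

## ERP and TFR conventions

Preprocessing: RT screen (drop missing, <0.6 s, >1.4 s; Oddball: targets
outside 0.1–1.3 s) first, then a zero-phase 4th-order Butterworth band-pass
0.5–20 Hz (forward–backward, odd-reflection padding of the full epoch
length), then subtraction of the −200–0 ms baseline mean per trial and
channel. Participants with <20 trials in any condition are flagged, not
dropped. Peaks are strict discrete local extrema on the 250 Hz grid, ties
to the earlier sample; the FRN latency search is 180–300 ms (reused to
center the 100 ms mean window, which is re-centered per participant from
the all-condition average, not per condition), the P2 search is
100–260 ms and must precede the N2 for the peak-to-peak measure, and the
P3 positive-peak search is 250–450 ms at Pz (our convention; only the
window width is inherited).

Morlet wavelets: 1–12 Hz in 1 Hz steps, Gaussian SD = 3/(2πf) (three
cycles; the FWHM endpoints sometimes quoted for this convention are
internally inconsistent, so the cycles definition is authoritative here).
Kernels are amplitude-normalized (|coefficient| estimates instantaneous
amplitude — irrelevant after dB conversion), signals reflection-padded by
2 s, and evoked power 10·log₁₀(|c|²/baseline) uses a per-trial,
per-channel, per-frequency arithmetic-mean baseline over −200–0 ms (a
per-participant-average baseline is available as an option); zero
baselines are floored at 10⁻²⁰ with a warning. Wavelets whose 10σ support
outlasts the 1.2 s epoch (1–2 Hz) are flagged edge-contaminated in the
container metadata.

**Measurement estimand.** Filtering and baselining reshape injected
bursts: the two-pass 0.5 Hz high-pass and the baseline window clip the
wide 3 Hz RewP envelope, attenuating its measured slope by ~20 %, and
filter ringing inflates the FRN slope by a few percent. Parameter-recovery
claims therefore target raw synthesized epochs, where the injected slope
is the exact estimand; analyses of preprocessed data recover the
*filtered* component, as they would on real recordings.

## Mixed-effects engine

Every grid point is fit with a linear mixed model with participant random
intercepts by maximum likelihood (not REML), so AIC = 2k − 2·logLik is
comparable across fixed-effect sets; k counts fixed effects plus the two
variance components (the same convention lme4 uses, verified in the test
suite). Wald two-sided t-tests use residual degrees of freedom
(n − fixed − groups). This is mildly anticonservative for predictors
identified partly between participants (effective df closer to the number
of participants); measured CI coverage at the injected coordinates is
≈93–95 %. Optimization tries lbfgs then powell; fits with non-finite
standard errors or log-likelihood (exactly-zero variance boundary) count
as non-converged, and such grid points are skipped and tallied
(`n_failed`), excluded from the FDR family. FDR families follow each
analysis's declaration — timepoints × predictors per channel for the
time-resolved analysis (50–500 ms grid, 113 points at 250 Hz); channels ×
predictors × windows (one family) for topographies (50 ms windows centered
on the peak-coefficient latencies 216/308/380 ms); timepoints ×
frequencies × predictors per channel for the TFR grid (0–500 ms, stride
configurable, 20 ms in desk-scale runs and recorded in the result
metadata). Valence splits refit only RPE magnitude and probability on the
negative (easy loss, easy neutral, hard loss) and positive (easy win, hard
win, hard neutral) outcome groups. Point-estimate regressions average
predictors within condition per participant; amplitude metrics keep the
random intercept, the within-participant-normalized FRN latency drops it;
missing peak-to-peak values are dropped listwise; FDR runs across model
predictors.

## Oddball benchmarks

Synthetic Oddball epochs reuse the synthesizer with stimulus-locked,
constant-driven components (N2b/N2c: 6 Hz, 250 ms, Fz, negative; P3a:
3 Hz, 350 ms, Cz; P3b: 3 Hz, 350 ms, Pz). Benchmarks are 50 ms mean
windows centered on the grand-average peak (negativity 0.2–0.3 s at Fz;
positivity 0.3–0.45 s at Cz/Pz; earliest extremum on ties).
Cross-task inter-participant correlations are Pearson r over shared
participants for each benchmark × Target Time condition (24 tests per
window, BH per window). What makes the two tasks correlate across people
is an explicit modeling assumption — a shared per-participant amplitude
factor — not something the analysis establishes.

## Problem sizes and what the tests show

Desk-scale defaults: pipelines run 12 participants × 600 trials at the
analysis electrodes; Monte-Carlo checks use 6–12 participants per seed
(50–100 seeds) — false-discovery control under a component-free null,
CI coverage of injected gains at the injected coordinates, the
overlap-artifact reproduction (a significant positive RPE-value
coefficient in the FRN window at Fz from purely non-valenced
magnitude-coded components, with opposite-signed magnitude effects in the
valence splits), and the leave-one-out AIC dissociation (dropping
magnitude hurts most at 216 ms/Fz, dropping probability at 380 ms/FCz).

Passing tests show the *machinery* is correct on data satisfying its
assumptions. The generator omits much of real EEG: no artifacts or
channel noise (so no ICA/interpolation stages), Gaussian RTs without
sequential dependencies or learning, linear feature–amplitude coupling,
spatially uncorrelated noise, and no real-data coefficient values —
magnitudes like the printed β_max of a recorded cohort are not
reproduction targets. Sign conventions also differ by domain: an injected
burst raises evoked power with its driving feature (positive power
coefficient) even when its voltage polarity is negative.
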