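# Methods

`erroraware` simulates a forced-choice error-awareness experiment and
re-analyzes it with the single-trial toolkit used in cognitive
electrophysiology. This note documents the generative model, the
estimators, the numerical choices, and what the simulations can and
cannot establish about real data.

## The task being simulated

On every trial of the number-judgment task a number between 34 and 76
(never 55) appears in a small or large font. Participants press button 1
for numbers below 55, button 2 for numbers above 55, and button 3 for
*targets*: the numbers 49 and 62, or any number repeating the previous
trial's number. After each response and a 500 ms blank, they judge their
own response as correct or incorrect within 1,200 ms. Errors followed by
an "incorrect" judgment are *aware errors*; errors judged "correct" are
*unaware errors*. The latency of the judgment serves as an inverse proxy
for confidence. A trial is *congruent* when font size matches numerical
magnitude (large ↔ above 55). Default composition: 1,000 trials = 800
standard + 100 number targets + 100 repeat targets, 50% incongruent, no
two targets adjacent, stimulus onset jittered over {300, 350, 400, 450}
ms. With a 1,200 ms response deadline and 1,200 ms judgment deadline the
total trial duration spans 3,200–3,350 ms.

Sequence construction: target positions are a uniform draw of k pairwise
non-adjacent positions (offset bijection); the congruency sequence is
built from alternating runs whose number is chosen so the four
transition counts (cc, ci, ic, ii) differ by at most 2, with run lengths
drawn as uniform random compositions. Every generated sequence is
re-checked by an exhaustive scanner (`check_sequence`).

## Generative behavioral model

Log RT is linear in the coded task factors (trial type, congruency,
jitter ±1; centered distance, log previous-judgment RT, log trial
number) plus Gaussian noise (SD 0.18 log-units ≈ 18% RT variability);
post-error slowing is an *additive* 11.5 ms on trials following aware
errors only, so the injected quantity is exactly the mean RT contrast
the PES analysis estimates. Accuracy is Bernoulli with a logit linear in
the same factors plus centered log RT (positive: slower → more
accurate). Awareness of an error is logistic in the trial's standardized
log RT (positive slope: aware errors are slower, as observed for this
task) and a latent error-evidence variable; judgment latency shortens
with evidence strength, making fast judgments a proxy for confidence.
Default rates reproduce the task's reported operating point: ~12.7%
errors overall, ~58% of them aware, ~93% of correct responses judged
correct. Misses (2%), multiple presses (1%) and invalid judgments (1%)
are injected so the exclusion rules have work to do.

The generator writes RT in ms; analyses model natural-log RT. Centering
of continuous regressors affects only the generative intercept, so the
slope betas recovered by the GLMs are directly comparable to the
injected values.

## Generative EEG model

Epochs are response-locked (−0.5 to 1.0 s, 500 Hz) on a 61-channel
montage of five concentric equidistant rings around Cz (4+8+12+16+20
electrodes at radii 0.2–1.0; exact cap coordinates are unpublished, and
only relative 2-D positions matter for topographies). Two components are
injected with Gaussian temporal envelopes and Gaussian spatial weight
maps peaking at Cz:

* a negative-going fronto-central component, center 70 ms, SD 25 ms
  (ERN-like), amplitude 5 µV on errors, 25% of that on correct trials;
* a positive centro-parietal component, center 230 ms, SD 60 ms
  (Pe-like), 6 µV on errors, 20% on correct trials.

On error trials the single-trial amplitudes are modulated additively by
awareness (±1 coding; gains 2 µV for the ERN, 3 µV for the Pe), centered
log judgment RT (−2.3 µV/log-unit on the Pe), and their interaction —
the same regressor structure the second EEG GLM estimates, so group
regression weights recover the gains directly (attenuated by the common
average reference, which removes the spatial mean of the weight map). A
9 Hz oscillation (3 µV, Gaussian envelope at 230 ms) carries the
phase-locking manipulation: trial phases are wrapped-normal with SD 0.6
rad on aware errors versus 2.5 rad on unaware errors. Noise is 1/f in
spectrum (FFT amplitude shaping), spatially correlated across the
montage (Gaussian kernel, length 0.35 head-radii, unit-norm rows), 10 µV
per channel.

What this emulates: realistic component timing/topography, single-trial
amplitude and phase variability, awareness/confidence coupling, 1/f
background. What it does not: ocular and muscle artifacts, volume-
conduction physics, non-stationarities, reference-electrode effects, or
inter-subject topography variability. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated model, not
robustness to every property of real recordings.

## Estimators

**Robust regression.** All single-trial linear models (behavioral RT
GLM, mass-univariate EEG GLMs, EEG→next-RT coupling) share one IRLS
implementation: Tukey bisquare weights with c = 4.685, scale
re-estimated each iteration as MAD-about-the-median / 0.6745, OLS start,
convergence when the largest coefficient change is below
1e-8·(1+max|β|), 200 iterations maximum. The implementation is
vectorized over response points (one batched weighted solve per
iteration; converged points freeze and leave the active set), which is
what makes fitting 61 × 750 electrode-timepoint regressions per subject
practical. Exactly fitting (noiseless) responses keep unit weights, so
the estimate reduces to OLS and recovery tests can demand 6+ significant
digits. Non-convergence (bisquare IRLS can cycle on adversarial draws)
or rank deficiency is flagged as "no model fit"; behavioral subjects
with no fit are excluded and counted, EEG points are masked. Approximate
t-values use the weighted-LS covariance; group-level inference never
relies on them alone.

**Behavioral GLMs.** RT model on log RT over current-correct and
current-error trials; logistic accuracy model (statsmodels ML fit) with
a log RT regressor and separation/non-convergence detection. Post-error
variants add previous accuracy (±1) and its interactions with
congruency, jitter and distance, restricted to trials following correct
responses or the selected error class (post-correct trials appear in
both variants by design). Trials lacking a defined regressor (first
trial's confidence) are dropped. Group level: two-sided one-sample
t-tests of per-subject t-values against zero, Bonferroni-corrected by
the regressor count, with 99% CIs; zero between-subject variance is
flagged degenerate rather than reported.

**Preprocessing.** Zero-phase Butterworth band-pass 0.5–42 Hz. The
filter order defaults to 8 because the design targets ≥20 dB suppression
of a 50 Hz mains probe while passing 10 Hz within ±1 dB after
forward-backward filtering; a 4th-order realization only reaches ~15 dB.
Common average reference subtracts the instantaneous channel mean.
Joint-probability artifact rejection scores each epoch by its mean
negative log empirical density (100-bin histograms) in two modes —
per-channel and pooled — robustly standardized (median/MAD, so that mass
contamination cannot mask itself); epochs above 4.5 SD are rejected, and
the threshold rises in 0.5 SD steps whenever more than 10% of epochs
would be lost. Response-locked re-epoching slices −0.5 to 1.0 s around
each response and subtracts the −200 to −50 ms baseline mean.
An ocular-cleaning hook accepts any EpochSet→EpochSet callable; no
decomposition is shipped (the synthetic data has no ocular artifacts),
which is a documented limitation for real-data use.

**Mass-univariate EEG GLMs.** GLM 1 (all trials): error (±1), distance,
log RT, congruency, log trial number. GLM 2 (error trials): awareness
(±1), confidence = log judgment RT, awareness × centered confidence,
plus the same confounds; trial type and jitter attach as optional
controls. Behavioral exclusions propagate to the EEG trials. Group
statistics: one-sample t over subject betas per electrode × timepoint;
Benjamini–Yekutieli FDR over the full electrode × time family per
regressor (valid under arbitrary dependence, hence conservative);
a per-regressor Bonferroni mask for thresholded topographies; 99% CIs.
Peak extraction takes the signed extremum of the group weight within a
latency window at a target electrode (default: the electrode with the
maximal GLM 1 error effect); exact ties resolve to the earliest latency
and are reported.

**Decoding.** Features are ±10 ms sliding means at 10 ms stride (11
samples at 500 Hz), z-scored globally and then per electrode × timepoint
over trials (this order is the default; the reverse is available since
the verbal description "across and within" is ambiguous). The
classifier is a linear SVM (C = 1). Cross-validation is 50 independent
random 90/10 holdouts — the prediction set never drops below 10 trials —
with class imbalance removed by randomly subsampling the majority class,
redrawn per fold. The holdout is *stratified* (equal class counts in the
prediction set): an unstratified test set anti-correlates with the
training majority and biases the null accuracy visibly below 50%, while
stratification makes the permutation chance level exactly 50% in
expectation. The searchlight repeats the analysis one electrode at a
time. The permutation test re-runs the full pipeline per permutation;
p = (1 + #{null ≥ observed}) / (1 + n). The config defaults to 2,000
permutations; 50,000 (publication scale) is a config change.

**ITPC.** Morlet wavelet phases (20 log-spaced frequencies 2–30 Hz,
3–8 cycles log-spaced) at one electrode; ITPC is the modulus of the mean
unit phasor over trials, and Rayleigh-Z = n·ITPC² corrects for the trial
count (E[Z] ≈ 1 under uniform phases for any n). Epochs are mirror-
extended before convolution; samples closer than one wavelet half-length
to a true epoch edge are flagged in a per-frequency validity mask rather
than trimmed — at 2 Hz and 3 cycles a hard trim (0.75 s) would consume
the whole epoch, whereas the 9 Hz probe band keeps a (−0.2, 0.7) s valid
window that comfortably contains the Pe range. The aware−unaware
contrast is taken on the Z maps; its 9 Hz time course is Pearson-
correlated with a supplied group regression time course (interpolated
onto the ITPC grid) over valid samples. A constant difference has no
defined correlation and is flagged degenerate. The regression course
used for this correlation is the awareness regressor of EEG GLM 2 (the
source analysis names an undefined "GLM 3"; the choice is a parameter).

**Coupling.** Next-trial log RT is robustly regressed on the error
trial's voltage per electrode × timepoint with controls (log judgment
RT, next trial's type/congruency/jitter), separately for aware and
unaware errors; since the voltage regressor varies with the point, the
design is built per point. Across subjects, awareness-regressor weights
at the group ERN and Pe peaks (fixed group latency/electrode — per-
subject peak picking would introduce selection bias) are Pearson-
correlated with the subjects' aware-variant PES weights. Sign
convention: the ERN is negative-going, so stronger ERN–PES coupling
appears as a negative correlation.

## Problem sizes and determinism

A single integer seed expands through `numpy.random.SeedSequence` into
independent substreams per stage and subject, so regeneration is
bit-identical and results are independent of execution order. The test
suite and the calibration script use deliberately scaled problem sizes
chosen to exercise every code path at full statistical resolution where
it matters: parameter recovery runs 30 subjects × 1,000 behavioral
trials with error-trial EEG at a 250 Hz analysis grid; the decoder
chance calibration runs 10 noise subjects × 120 balanced error epochs ×
200 permutation replicates with 8 folds and 25 ms feature stride (the
chance level is invariant to fold count and stride); null calibrations
of the FDR and group tests use 200–1,500 replicates on small grids. The
demo pipeline configuration (a few subjects × a few hundred trials)
completes in well under a minute per subject on one CPU.

## Known limitations

* No artifact classes beyond stationary 1/f noise; the rejection stage
  is validated on constructed outliers only.
* The logistic accuracy model is ordinary ML, not a robust variant; the
  robustness of the published "robust" logistic fit is unspecified, and
  separation is handled by exclusion rather than penalization.
* BY-FDR over the full spatiotemporal family is conservative; the
  per-electrode family option changes sensitivity, not validity.
* Group topography variability is absent, so cross-subject decoding or
  electrode-wise generalization claims are out of scope.
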