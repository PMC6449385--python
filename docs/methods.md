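# Methods

This note describes, in the package's own terms, the statistical methods
implemented in `cogdbs` and the design choices behind them. The toolkit
analyzes a within-subject DBS ON/OFF manipulation during a conflict task
(MSIT with emotional background images), from single-trial reaction times
through induced prefrontal oscillatory power to a per-subject clinical
biomarker. Because real patient recordings cannot be redistributed, the
package ships a synthetic-cohort generator whose defaults mirror the study
conditions, and every estimator is validated against analytic or exhaustive
oracles plus calibration and parameter-recovery suites.

## Synthetic cohort (`cogdbs.simulate`)

**Trial sequences.** Each block interleaves control and interference MSIT
trials over emotional background images. Sequences are generated under the
task's counterbalancing constraints — no three consecutive trials may share
valence category, interference status, or response finger — by randomized
greedy assignment with backtracking and bounded restarts; infeasible
specifications raise rather than silently violating constraints. Image
pools are split into two rating-matched halves (DBS ON vs OFF) by pairing
images adjacent in valence rank and assigning one of each pair to each
half, which minimizes the squared difference of sorted valence profiles.

**Reaction times.** RTs are gamma distributed with identity-link mean
`intercept + subject offset + 224·interference − 34·DBS` (ms) and shape 16
(CV ≈ 25%), matching the skewed, strictly positive character of conflict
RTs. Errors and omissions are injected at the study's observed rates, and
post-error trials are flagged for exclusion.

**EEG epochs.** Label time courses are 1/f spectral-shaped noise plus (a)
a phase-locked evoked response following stimulus onset and (b)
non-phase-locked theta bursts: 300 ms Hanning-windowed 6 Hz oscillations
with random phase per trial and jittered centers, whose amplitude gains
(in dB) depend on interference and DBS state. Random phase makes the
bursts cancel in the trial average, so they are recoverable only through
single-trial time-frequency analysis — the property the induced-power
workflow is designed to exploit.

**Resting traces.** Continuous rest is 1/f noise plus stochastic
narrowband theta (band-passed white noise, theta ± 1.5 Hz). Stochastic
rather than sinusoidal theta matters: a coherent sinusoid gives every
one-second epoch of a trace nearly the same power estimate, violating the
independence assumptions of rank tests across epochs. With narrowband
noise, epoch-level theta power decorrelates within a fraction of a second,
and the ON-vs-OFF Mann–Whitney p-value is uniform under the null (verified
over 200 seeds).

**Clinical linkage.** Per-subject theta change and MADRS improvement are
drawn from a bivariate normal with correlation `biomarker_r` (default
0.76); a conditional variant generates improvement given theta changes
measured from the EEG stage, so the end-to-end pipeline sees a realistic
noisy linkage rather than a wired-in answer.

## Behavior (`cogdbs.behavior`)

Trials are quality-controlled by dropping omissions, errors, and
post-error trials, then removing per-subject RT outliers below a gamma
density of 0.005 (gamma fitted per subject on the remaining trials, RT in
seconds). The RT model is a gamma GLM with identity link — effects are
additive in milliseconds while respecting RT positivity and
variance-mean scaling. Subject random intercepts are approximated by
per-subject dummy intercepts, appropriate for this design where every
subject contributes hundreds of trials and interest is in the shared fixed
effects. Continuous predictors are standardized to [0, 1] for fitting and
coefficients are reported back in natural units per raw predictor unit.
Fixed effects are chosen by forward stepwise AIC over candidate terms
(interference, DBS, valence, arousal, interference × DBS) with nuisance
terms (trial number) always included; a term enters only if it lowers AIC,
i.e. if its deviance gain exceeds 2. Inference on coefficients is by Wald
t statistics. ON-vs-OFF error rates are compared with an exact conditional
binomial test (conditioning on the total number of errors).

## Induced spectral power (`cogdbs.spectral`)

Epochs exceeding an absolute amplitude threshold are rejected. Induced
(non-phase-locked) power is isolated by subtracting the condition-specific
ERP (per subject × DBS state × interference) from each trial before
wavelet decomposition. Time-frequency analysis uses Morlet wavelets on 25
log-spaced frequencies from 2 to 50 Hz with 3 cycles; reflection padding
controls edge artifacts, and a per-frequency validity mask (±half the
wavelet length) marks samples that remain edge-contaminated. Power is
averaged into theta (4–8 Hz), alpha (8–15 Hz), and beta (15–30 Hz) bands
and converted to dB relative to each subject × DBS-state mean baseline
power over −0.5 to −0.1 s; stimulus-locked baselines can be reused for
response-locked data. Resting analyses cut sixty one-second epochs per
state, estimate power with multitaper spectra (8 Hz bandwidth), and
compare ON vs OFF epoch-level theta with a two-sided Mann–Whitney test.

## ROI collapse (`cogdbs.roi`)

Vertex bundles are collapsed to one ROI time course by `pca_flip`: the
first right singular vector of the vertex × time matrix, scaled so mean
output power equals mean per-vertex power, with sign set by the
largest-magnitude element of the first left singular vector. Unlike plain
averaging, this does not cancel anti-phase vertices (a consequence of
source-orientation sign ambiguity) and preserves bundle power exactly for
rank-1 bundles.

## Cluster statistics (`cogdbs.cluster`)

Single-trial band power (or voltage) is analyzed with a mass-univariate
sliding regression: at each timepoint, trials are regressed on
standardized predictors (interference, DBS, valence, arousal, trial
number, interference × DBS) after subtracting each subject's all-trials
mean time course (the fixed-effect analogue of a subject random
intercept). Contiguous same-sign runs where |t| exceeds the two-sided
α = 0.05 critical value, lasting at least 50 ms, form clusters summarized
by signed t mass. Significance comes from a permutation distribution of
the maximum |cluster mass|: the predictor of interest is permuted within
subject (Manly scheme by default; Freedman–Lane residual permutation is
available), with `p = (1 + #{null ≥ |mass|}) / (n_perm + 1)` so p is never
exactly zero. Family-wise error of this procedure is verified to be
nominal (within [0.03, 0.07] at α = 0.05) on 500 null datasets. Cluster
p-values are Benjamini–Hochberg corrected across ROIs × bands per
predictor. A cluster-mass-fraction summary reports the percentage of
summed |t| mass falling inside a time window (e.g. stimulus onset to mean
RT, the "decision window").

## Biomarker (`cogdbs.biomarker`)

The candidate electrophysiological biomarker is the trapezoidal integral
(dB·s) of each subject's ON − OFF theta difference wave over the window of
the group-level DBS theta cluster (ventrolateral prefrontal label by
default); the behavioral comparator is the mean ON − OFF RT change.
Each is correlated with MADRS improvement using Pearson r with a
Fisher-Z p-value (`z = atanh(r)·√(n−3)`), displayed with a Huber robust
line, and given percentile bootstrap CIs over subjects — all statistics
reuse the same bootstrap draws so intervals are comparable. Classification
of clinical response (≥50% MADRS drop) and of hypomania (with row-wise
deletion of missing ratings) is summarized by ROC AUC, which equals the
normalized Mann–Whitney U (verified against exhaustive pair counting).

## Pipeline (`cogdbs.pipeline`, `cogdbs.cli`)

`run_all` chains simulate → behavior → spectral → cluster → biomarker →
resting, streaming EEG one subject at a time in float32 to bound memory,
writing tidy CSV/JSON outputs, figures, and a provenance stamp (package
version, config hash, seed). Stages can be skipped; skipping propagates to
dependent stages. The `cogdbs` command line exposes each stage and
`run-all`. All randomness flows from a single seed through named
`SeedSequence` streams, so every output is bit-reproducible.

## Validation strategy

The test suite favors oracles over snapshots: exhaustive enumeration
(permutation p-values, Mann–Whitney U, bootstrap resamples, image-split
optima), closed forms (OLS t, BH adjustment, gamma CV law, Fisher-Z
worked example), calibration laws (uniform null p-values, nominal
family-wise error, the χ²₁ > 2 stepwise-AIC inclusion rate), and
parameter recovery at the generating values (±3 SE). Generator defaults
are treated as fixed study conditions; test fixtures vary only in
replication scale.
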