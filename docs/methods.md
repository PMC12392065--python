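# Methods

This note documents the models behind `mifind`: what the synthetic
generators assume, which parameters matter, and the numerical and design
choices made where the experimental literature leaves the implementation
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Generative model for MEP trials

A simulated participant is a set of multiplicative gains acting on
per-muscle baseline MEP amplitudes. On a trial with imagery cue *c*,
muscle *m* yields

    amplitude = baseline(m) · gain(c, m, session) · ε,

where `gain` is `facilitation_target` when *m* is the cued finger's muscle
(times `session_gain` post-training), `suppression_nontarget` for the other
two muscles, and 1 on rest trials. The noise ε is lognormal with unit mean
and coefficient of variation `mep_cv` (σ² = ln(1+cv²), µ = −σ²/2): MEP
amplitudes are positive and right-skewed, and the mean-preserving
parameterization makes the expected normalized MEP equal the gain for any
cv, which is what the pipeline-recovery tests exploit.

Defaults — baseline 0.8/1.0/0.6 mV (thumb/index/little), cv 0.3,
facilitation 1.3, suppression 0.9, session gain 1.2 — place the session
mean MEP target ratio near 1.44 pre- and 1.73 post-training, i.e. in the
1–2 range a successfully trained participant occupies. No published
effect-size anchor exists for these gains; they are config-exposed and were
fixed once, before any calibration test was run.

Background EMG rms per muscle is lognormal around 2 µV (clean trials); with
probability `contamination_rate` one right-hand muscle instead draws
uniform 8–15 µV. This mixture gives both exclusion rules work: the 7 µV
ceiling catches contaminated trials, the ±2.5 SD band catches the tail of
the clean distribution.

## EMG processing

Filters are not specified beyond their band edges in the source protocol,
so the realization is a package choice: 4th-order Butterworth 30–800 Hz
applied forward–backward (`sosfiltfilt`, zero phase) and a 2nd-order IIR
notch at 50 Hz with Q = 30 (background windows only). Tests pin the
attenuation *contract* (≥30 dB at 50 Hz, passband preserved within 5%),
not the realization. Note a physical limitation: a Q = 30 notch has an
impulse response of roughly 0.2 s, longer than the 100 ms background
window, so the −30 dB figure holds at steady state (verified on the central
section of a long window); on windowed segments the notch only damps the
hum. Practitioners who filter continuous recordings before windowing are
unaffected.

Block baselines are the per-muscle median of rest trials 2–10 (the first
rest MEP is inflated by stimulus novelty and discarded); a non-positive
median flags the block degenerate and aborts normalization rather than
propagating infinities. The ±2.5 SD exclusion population is the session's
rule-1 survivors, per muscle — the per-block alternative is not offered.
The session summary uses the arithmetic mean of per-trial ratios; a
geometric option exists (ratios are log-scaled) but is off by default.

## Neurofeedback scoring and schedules

Success and star comparisons are strict: a normalized target MEP exactly
equal to 1, or tied with a nontarget, fails (the protocol language —
"exceeded", "higher" — implies strict inequality). The star rule follows
the methods text (target > 150% of *each* nontarget); an absolute variant
(target > 1.5) is available as `star_rule="absolute"` because the two
readings appear in different places in the source material. The gate
restarts the imagery clock at the end of a contiguous excursion, one
restart event per excursion; excursions beginning within 0.5 s of the
scheduled pulse are ignored. Jittered durations are uniform over their
stated intervals.

Schedules: session 1 cues one finger per pair of consecutive blocks;
sessions 2 and 3 use runs of 8 and 4 cues; session 4 and the feedback-free
measure are fully interleaved. Every block is 10 rest cues + 24 imagery
cues with each finger cued 8 times (sessions 2–4), counterbalanced by
seeded permutation.

## Threshold hunting

The hunting engine is fixed-slope maximum likelihood: the logistic slope is
assumed (default 2 %MSO), not estimated — matching MTAT-style adaptive
procedures where only the threshold is hunted. The likelihood is maximized
over a 0.1 %MSO grid spanning the searchable range (default 20–90 %MSO),
ties broken toward the lower intensity; recommendations are rounded to the
1 %MSO stimulator resolution. All-positive or all-negative histories are
unidentifiable and return a boundary estimate with a non-converged flag.
The convergence diagnostic (fraction of positive responses in the last five
trials within [0.2, 0.8]) mirrors the experimenter's visual check; block
repetition on non-convergence is left to the caller.

Start intensity (40 %MSO), range and slope are defaults of this package,
not claims about the original hardware setup. Simulation (500 tracks of 20
counted trials, threshold 45, slope 2; see the acceptance suite) observed
|bias| ≈ 0.02 %MSO and SD ≈ 1.1 %MSO; the frozen test bound is SD < 2.5.

The maximum-MEP procedure discards the first of 10 recruitment pulses and
removes values more than 2.5 SD *above* the mean of the remaining nine
before taking the maximum — "without outliers" is otherwise undefined, and
2.5 SD reuses the protocol's only other outlier definition.

## Pattern generation and multivariate analyses

Pattern datasets are run × condition × trial × voxel beta arrays plus a
residual array sharing the same noise covariance (10× as many residual
samples as trials, so shrinkage has data to work with). Noise is stationary
Gaussian with voxel variances drawn uniform [0.5, 1.5]·sd² and exponential
spatial correlation exp(−d/ℓ), ℓ = 2 voxels by default. Finger-mean
directions are drawn once per subject; imagery means are scaled by the
session's `signal_scale` (defaults 0.3 pre, 0.45 post — distinctness
increases with training), execution means share a `shared_exec_imagery`
fraction of variance with imagery via square-root weighting
(√s·z_imagery + √(1−s)·z_independent) so their magnitude does not depend on
s, and keep the pre-training scale in both sessions (training targets
imagery). Trial counts mirror the task design: 48 imagery trials per finger
and session over 4 runs, 30 execution trials per finger and session over 6
runs; execution trials for middle and ring fingers are never generated
because they are not analyzed.

The covariance estimator is analytic shrinkage toward the sample
covariance's own diagonal (Schäfer–Strimmer weights), not toward a scaled
identity: prewhitening should preserve voxel-specific variances. A small
ridge (1e-12 of the mean variance) keeps the estimate strictly positive
definite with degenerate inputs. Residuals are centred within run and
pooled across runs before shrinkage; per-run estimation is not implemented.

Crossnobis distances are computed on per-run condition means, normalized by
voxel count P (the convention of standard RSA toolboxes), averaged over all
ordered fold pairs. Negative single estimates are preserved — clipping
would destroy the unbiasedness that makes the null tests meaningful.
Decoding operates on single-trial betas; the two extraction paths
(run means for RSA, single trials for decoding) are deliberately distinct.
The SVM is `SVC(kernel="linear", C=1, tol=1e-6)`; the fixed tolerance makes
fits bit-reproducible on a given dataset. Scaling is fitted on training
folds only for cross-validated decoding, and per task (on the full task
data) for cross-task transfer. Permutation nulls shuffle labels (class
counts preserved): test labels only for cross-task transfer, all labels
with refitting for within-task cross-validation — the second is exact but
expensive and is exposed separately.

## What the generators do not emulate

No hemodynamic response or GLM structure (betas are emitted directly), no
temporal autocorrelation within runs, no realistic EMG spectra beyond what
the filter tests need, no session-to-session drift in coil position, no
middle/ring execution conditions. A green test therefore establishes that
the *analysis chain* is correct on data satisfying its stated assumptions,
not that those assumptions hold for any particular recording.

## Calibration caveat

The empirical p-value (#{null ≥ true}+1)/(n_perm+1) is conservative under
ties. Decoding accuracies are discrete (multiples of 1/n_test), and on
pure-null data the SVM occasionally predicts near-constant labels, making
many permutation scores tie with the true score; the p-value distribution
is then slightly super-uniform (mean ≈ 0.51–0.55 in our null studies)
rather than exactly uniform. The calibration test verifies uniformity by
KS test at its stated threshold; users comparing very small effect sizes
should expect the test to err on the conservative side.
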