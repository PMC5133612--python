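# Methods

`panthoot` re-implements, as a tested pipeline, an analysis of which phases of
the chimpanzee pant hoot carry information about the caller. A pant hoot has
four acoustically distinct phases produced in fixed order — introduction
(soft, low-frequency "hoo" units), build-up (accelerating low-amplitude
pulses), climax (loud, high-frequency screams), let-down (faint pulses
resembling the build-up) — and a call counts as a pant hoot only if the
climax is present. The question the pipeline answers is: which phases carry
acoustic correlates of caller identity, age class, social status (Elo rank
class), and behavioural context (travel vs feeding)?

Because the original field recordings are not publicly deposited, the
pipeline ships with a synthetic call generator whose statistical structure
matches what the analysis assumes; the generator is first-class, tested code,
and all quantitative checks in this package run on it. What passing tests
show is therefore that the *pipeline* behaves correctly (chance level without
signal, localized recovery with signal), not that real pant hoots carry the
signatures — that is the field result the pipeline emulates.

## Feature front end

Each phase clip is framed into 30 ms Hamming windows with 50% overlap. Frame
starts sit on the exact 15 ms hop grid in time (not on a rounded sample hop),
so the frame count is `floor((clip_ms − 30)/15) + 1` at any sample rate. Per
frame: FFT (zero-padded to the next power of two), power spectrum, a 32-band
triangular mel filterbank spanning 1–20050 Hz, log band energies (floored at
1e-12 to keep silence finite), and an orthonormal DCT-II. All 32 cepstral
coefficients are kept — no truncation — and delta coefficients (regression
slope over ±2 frames with edge replication) double the per-frame dimension
to 64.

The mel scale is the HTK convention `m = 2595·log10(1 + f/700)`; the band
centers are the 32 points linearly spaced in mel between m(1 Hz) and
m(20050 Hz) inclusive, with triangular weights anchored at neighbouring
centers (virtual edges at the range ends, peak weight 1, no area
normalization). This choice reproduces the reference 32-element center
arrays on both the mel and hertz scales to the printed precision; the
alternative Slaney-style piecewise-linear convention does not come close.
The 20050 Hz ceiling is implemented as printed even though it is oddly near
(but not equal to) the 22050 Hz Nyquist of 44.1 kHz audio. When the
filterbank is built for a lower sample rate, bands above Nyquist simply
collect no energy; the scaler downstream maps such constant dimensions to
zero, so they are harmless.

## Segments and normalization

Classification never sees whole clips. Per call, exactly one segment of a
predetermined window length (50–3250 ms in 50 ms steps) is cut from the
clip's feature matrix at a random (or, in the time-course analysis, fixed)
onset, flattened frame-major. Windows longer than the clip are padded with
NaN markers. Features are then range-scaled to [0, 1] and mean-normalized —
both fitted on the training portion only and applied unchanged to test data
(test values may leave [0, 1]; they are not clipped). Padded positions are
imputed as 0 *after* normalization, i.e. at the per-dimension scaled mean,
the least informative constant. The scaler records a state hash so that
re-fitting on test data (snooping) is detectable.

## Classification

Soft-margin RBF SVMs, one-class-versus-rest. For each (attribute, phase)
cell, a ~10% tuning subset of clips is set aside; (C, γ) are grid-searched
over C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} and γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³} (110 pairs) by
5-fold cross-validation on that subset (folds degrade to the smallest class
count when the subset is very small; classes with a single member are
dropped from CV). Ties break toward smaller C, then smaller γ. The tuning
subset is then discarded; hyperparameters are tuned once per (attribute,
phase) and reused across window lengths.

Each one-vs-rest comparison balances the pooled rest class by random
subsampling to the target-class size — without balancing, a 1-vs-9 identity
comparison would have a 90% trivial baseline and "percent correct" would not
be comparable to the stated 50% chance level. A single random permutation
drives both the subsampling and a per-class 80/20 split, which makes the
train and hold-out sets exactly balanced (a no-signal classifier scores 50%
in expectation, not 4/9 — the artifact an odd balanced hold-out would
produce) and makes the score invariant under label flips, so the two
complementary comparisons of a 2-class attribute are identical and their
mean equals either one. Classes with fewer than 5 members cannot support
the split and make the cell *missing* (NaN), never zero.

Per-cell randomness is derived from the master seed through CRC32-hashed
spawn keys, so cells are independent but individually reproducible; the
whole pipeline is bit-reproducible for a fixed seed.

The SVM itself is scikit-learn's libsvm binding. The test suite verifies it
against an independently written dual-QP solver (SLSQP on the box-constrained
dual) on small toy sets: hold-out predictions must agree exactly at fixed
(C, γ).

## Indices

For each (attribute, phase): occurrence counts = number of window lengths
scoring ≥ 75, 80, 85, 90, 95% correct ("≥" as the operative definition;
for continuous scores the ≥/> distinction is immaterial). Prominence is the
mean of the five counts. Counts are summed over thresholds *before*
normalization (the aggregation order is configurable since it is not
uniquely determined by the verbal definitions): modality specificity
normalizes each attribute's row across phases to 100% ("which phases carry
this attribute"), phase specificity each phase's column across attributes
("which attributes this phase carries"). The window-bin profile averages
scores in five window classes ([50:700], [750:1350], [1400:1950],
[2000:2600], [2650:3250] ms — 14, 13, 12, 13, 13 lengths) and normalizes
within each attribute row to sum to 100. All-zero slices are undefined
(NaN), never 0/0.

## Time course

The classification is re-run with onsets fixed at 0–3000 ms in 100 ms steps,
relative to each *phase clip's* own onset (the original display aligns to
phase onsets). Scores are averaged over the window lengths evaluable at each
onset (the count is recorded), and the five best onsets per (attribute,
phase) are flagged, ties toward earlier onsets.

## Phase presence (composition)

Presence of the build-up and of the let-down are each modelled as
mixed-effects logistic regressions: fixed effects context (0 = travel,
1 = feeding), age in years (continuous) and Elo rank position (numeric),
plus a random intercept per caller — the only plausible grouping factor.
The marginal likelihood integrates the random intercept by 25-node
Gauss–Hermite quadrature and is maximized by L-BFGS-B with σ ≥ 0; Wald
standard errors come from the fixed-effect block of the numerical Hessian
with σ held at its estimate. This maximum-likelihood fit is written in the
package because the available Python binomial mixed-model backends are
approximate-Bayesian (mean-field) and understate the coefficient spread by
roughly a factor of two at these sample sizes, which would wreck interval
coverage; the fit is cross-checked against `lme4::glmer` in the test suite
and agrees to ~1e-2 on coefficients and standard errors. (Quasi-)separation
is reported as a diagnostic flag, not a crash.

The model deliberately does not try to reproduce the field study's coefficient
values — the raw field data are unavailable — but the generator's default
presence rates (build-up 95.58% / 73.17%, let-down 93.52% / 54.88% in travel
/ feeding) imply context log-odds contrasts of −2.07 and −2.47, and the
fitted context coefficients must be negative (feeding calls less likely
complete), matching the direction reported in the field.

## Synthetic generator

Each phase is an additive harmonic source (up to 24 harmonics, power-law
spectral tilt, Gaussian formant-like resonance) under a pulsed raised-cosine
envelope plus a small seeded noise floor, at 44.1 kHz (the standard field
recorder rate; the filterbank ceiling needs Nyquist ≥ 20050 Hz). Default
phase durations are 4 / 2.5 / 2 / 1.5 s (introduction longest, the stated
ordinal fact) with ±30% lognormal jitter. Attribute signatures enter as
additive parameter offsets scaled by a per-(attribute, phase) effect size:
identity through the caller's idiosyncratic F0 and vocal-tract traits, age
and rank through monotone offsets of F0, tilt and resonance position,
context through pulse rate, tilt and resonance. With all effect sizes zero,
the waveform distribution is identical across callers and contexts —
bit-identical for a fixed seed — which is what makes the chance-level null
test meaningful. The default signature placement mirrors the field
findings (identity → introduction + climax, age → introduction + build-up,
rank → climax, context → let-down) and is fully overridable. Omission of
the build-up and let-down is independent Bernoulli per phase given the
context (no dependence between the two is assumed). The generator makes no
attempt at perceptual realism; only statistical separability matters.

The reported corpus counts are inconsistent between sections (travel 139 /
feeding 82 in one place, the reverse in another); the generator's default
context mixture uses travel = 139/221 and both weights are parameters, so
the contradiction is exposed rather than resolved.

## Problem sizes used in the checks

The shipped checks are sized to desk scale: the chance-level null uses 60
calls and 20 repeats at one window length; the signature-recovery check uses
10 replicate corpora of 221 calls (the reference corpus size) with three
window lengths, one repeat, and the two signal-bearing attributes; the
presence-model recovery uses 100 simulated corpora of 400 calls (composition
only, no audio); the SVM oracle checks use ≤ 40-point toy sets. The full
65-window × 31-onset sweep is available through the CLI and `RunConfig`
defaults but is not exercised end-to-end in the tests.

## Known limitations

* The generator's phases are statistically separable caricatures; effect
  sizes are in arbitrary units calibrated only by the monotonicity and
  recovery tests, and transfer of accuracy figures to real recordings is
  not claimed.
* Hyperparameter tuning on very small subsets (~6 clips) is close to
  uninformative and falls back on the smaller-C tie-break; with corpus-sized
  datasets it selects sensible pairs.
* `one-vs-rest` is implemented as stated ("ID1 versus others"); all-pairs
  comparison is not implemented.
* The time-course averages include padded (NaN-imputed) windows exactly as
  the main sweep does; onsets beyond every clip of a phase are missing cells.
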