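# Methods

This note documents the models behind `sfemg`, the defaults and why they
were chosen, the numerical choices, and what the synthetic data does and
does not emulate.

## Signal model (waveform tier)

A single-fibre action potential (SFAP) is modelled as the first derivative
of a Gaussian: a biphasic wave whose positive lobe peaks `rise_time` before
the negative peak. With `s = rise_time/2`,

    w(t) = −A · √e · u · exp(−u²/2),   u = (t − t_c)/s,  t_c = latency − s,

so the negative peak has magnitude `A` (µV) at `latency` and the rise time
(positive peak → negative peak) equals the configured value. Morphology is
a modelling choice: the selection rules the analysis implements constrain
rise time, amplitude and unitarity, not the analytic form. Defaults
(`amplitude 300 µV`, `rise_time 150 µs`, latencies 3–5.5 ms) are typical of
near-electrode fibres in a small facial muscle (orbicularis oculi).

Per sweep, the response latency is `mean_latency + N(0, jitter_sd)` and the
response is omitted with probability `block_prob` (Bernoulli per stimulus —
at a continuous 10/s stimulus rate there is no velocity-recovery-function
memory to model). Additive noise is Gaussian, default 10 µV RMS, which
keeps the 100 µV amplitude criterion meaningful (SNR ≈ 30 for a default
fibre; the qualification contract is validated down to SNR 10).

**Band-limiting.** Both waveform and noise are restricted to the amplifier
band (1–10 kHz) by zero-phase spectral masking with raised-cosine
transitions placed *inside* the passband edges. The generator synthesizes
the amplifier's output rather than modelling its analog filter; the mask
guarantees < 1% out-of-band energy (tested) and leaves every unitary
potential with a phase-locked ~15–20% undershoot/overshoot pattern that the
qualification stage must — and does — treat as part of the waveform.

**Artifact classes.** `positive_going`: sign-flipped template (damaged
fibre). `composite`: a second template at a fixed 100–400 µs offset with
small (15 µs SD) independent jitter — consistent sweep-to-sweep but
non-unitary. `threshold_hovering`: normal jitter (5–25 µs SD) with 10–50%
blocking — the signature of stimulation hovering at the fibre's threshold.
`latency_jump`: one ≥ 600 µs step in mean latency at a random sweep
(electrode movement). `overlapping`: a companion fibre within ±50 µs mean
latency with independent full-scale jitter — the merged potential's depth
and width beat sweep-to-sweep.

## Qualification

Detection runs per sweep on a Savitzky–Golay-smoothed trace (window 7,
order 3). A response is present iff the dominant trough exceeds 5× the
baseline noise RMS (estimated from the first millisecond, before any
physiological latency) *and* the local peak-to-peak exceeds 100 µV. The
published criteria select fibres; the noise-relative clause is what stops
noise spikes counting as responses on blocked sweeps.

* **Peak latency** is refined by a least-squares parabola over ±4 samples
  around the discrete minimum. A 3-point parabola was rejected: with 10 µV
  band-limited noise its vertex scatter is comparable to a 10 µs jitter
  scale, while the ±4-sample fit leaves ~2 µs error SD — small against even
  the tightest jitter of interest, at negligible cost. Any waveform-shape
  bias of the fit is constant across sweeps and cancels in the MCD.
* **Polarity** is judged by lobe order: a dominant positive lobe *after*
  the trough (with none before) marks a positive-going potential. This is
  what makes the sign-flip observable for a symmetric biphasic template,
  and matches practice: damaged fibres show an initial positive deflection.
* **Rise time** is the preceding positive peak → trough interval, falling
  back to the 10%-of-depth onset when no positive peak rises above noise.
  The 0.5 ms bound is applied at fibre level to the median across present
  sweeps, as is the amplitude criterion.
* **Shape analysis** aligns ±1 ms snippets on the measured trough; the
  shape score is the Pearson correlation with the pointwise-median snippet
  mapped to [0, 1] ((r+1)/2; threshold 0.95, i.e. r = 0.9; a fibre is
  inconsistent when > 10% of sweeps fall below). The notch/shoulder screen
  runs on the median snippet between the positive lobe and ~0.5 ms past the
  trough, demanding prominence ≥ 22% of depth so band-limit ringing never
  fires it; a shoulder is an interior local maximum of the rising-limb
  derivative.
* **Overlap evidence** is (a) ≥ 3 sweeps with two distinct supra-threshold
  troughs, or (b) trough half-width SD > 25 µs, or (c) trough-depth
  CV > 0.07. Clean fibres sit near 10 µs / 0.04 on (b)/(c) regardless of
  jitter; merged overlapping fibres beat well above both.
* **Latency jumps** are flagged when the stride-1 running median (window
  10 sweeps) shifts by > 500 µs across one window — the stride-1 form
  guarantees a step lands fully across some pair wherever it falls.
* **Threshold-hovering** fires when any stimulus blocked while the
  provisional MCD is ≤ 33.4 µs; it can never fire without blocking.
* **Response floor**: shape statistics and jitter need ≥ 5 present sweeps
  (MCD itself needs 2; 5 guards the shape statistics). Zero responses are
  *not* a recording failure: a completely blocked fibre is a valid clinical
  finding and enters the metrics at the 200 µs cap. One to four responses
  reject as `too_few_responses`.

Reasons accumulate (a fibre can be, e.g., composite *and* hovering);
classification never mutates measurements and is idempotent. A
`criteria_not_met` reason covers fibre-level amplitude/rise-time failures.
All thresholds live in `QualificationConfig`.

At default thresholds the confusion matrix against generator ground truth
is: clean acceptance ≥ 95%, and every artifact class rejected with its
matching reason in ≥ 90% of seeds (tested at 200 fibres/class).

## Jitter metrics

MCD is computed over *present* sweeps in acquisition order; consecutive
pairs spanning blocked sweeps are included by default (the latency process
is exchangeable across gaps under the iid model) but are counted, and an
option excludes them. The blocking denominator is all delivered stimuli.
The 200 µs cap applies at fibre level *before* session medians — the only
way a group median of 200 µs is attainable — and requires blocking
alongside extreme jitter; an uncapped MCD > 200 µs without blocking passes
through unchanged. Session abnormality uses the median rule by default
(medians are what the analysis reports throughout); `any_fibre` and
`fraction` rules are selectable because the per-patient "increased jitter
within 24 h" call is not otherwise pinned down.

## Cohort model (latency tier)

Whole cohorts are simulated at the *latency tier*: per-sweep latencies and
presence flags are drawn from the same latent model as the waveform tier
and fed through the package's own `measure_fibre`/`summarize_session`.
This is the deliberate scaled-down problem size that makes repeated-seed
studies (50–200 cohorts) cheap; the waveform tier is exercised end-to-end
separately. Consistency between tiers is inherited by construction (same
latent draws semantics) and checked by the estimator-recovery tests.

Each patient draws an IMS label (prevalence 63/120 = 0.525), a lognormal
severity multiplier (σ = 0.5 for IMS+, 0.15 for IMS−), and a session
schedule: first test within 4–23 h of ingestion, except a 45% fraction of
delayed transfers first tested at 24–72 h; subsequent tests every
~48 ± 7 h until discharge or death. Group median courses (hours → µs):

* IMS+ jitter: 260 → 95 → 32 → 29.5 → 29 → 28.5 at 24/48/72/96/144/216 h,
  times the severity multiplier (tapered toward exponent 0.45 after 72 h as
  individual recovery converges), floored at the normal level (~30 µs).
  Day-1 targets sit above the cap, so most day-1 fibres are capped and the
  group median equals 200 µs exactly; blocking follows its own course
  (90% → 2% over the same span), with a matching fraction of completely
  blocked fibres, putting the day-1 median fibre blocking near 100%.
* IMS− jitter: ~30.5 → 28.5 µs, truncated at 33.4 µs: IMS− *target*
  trajectories never exceed the normal limit by design; realized session
  medians scatter above it through fibre sampling, which is what gives the
  simulated IMS− group its early false-positive fraction.

Severity is linked to the clinical covariates: IMS− length of stay grows
with severity (exponent 6 on the multiplier) and delayed IMS− transfers
skew sicker (+1 SD), so the IMS− patients still measurable at 72 h and
beyond are the near-boundary ones. Deaths hit 25.4% of IMS+ patients at a
median 72 h; half the fatal courses stay at admission-level jitter
throughout, half mimic recovery and relapse within 36 h of death. For
surviving intubated IMS+ patients, extubation time equals the realized
jitter-normalization time plus `N(0, extubation_noise_sd)`; under the
approximation r ≈ σ_T/√(σ_T² + σ_ε²) (σ_T the spread of normalization
times), the shipped σ_ε = 148 h targets a cohort-level Pearson r ≈ 0.49,
verified at 0.490 over 200 seeds of 60-patient cohorts. Admission red-cell
AChE is near-zero exponential for IMS+ and a zero-inflated exponential
(50% zeros, scale 2.5 U/gHb) for IMS−.

**Preset calibration and a deliberate trade-off.** The preset is
calibrated so the default cohort reproduces the reported contrast pattern:
IMS+ vs IMS− jitter significant at < 24, 24–48 and 48–72 h and
non-significant at 72–96 h and beyond under the step-down procedure
(≥ 90% of 50 seeds; 50/50 in development). A group median that stays
abnormal until day 9 is not jointly attainable with a non-significant
72–96 h comparison under this windowing — late non-significance requires
the fast-recovering half of IMS+ patients to overlap the near-boundary
late IMS− patients. The preset resolves toward the tested contrast
pattern: the IMS+ *group median* touches normal around day 4 while the
slowest quartile (and the fatal courses) remain abnormal past day 9,
consistent with individual jitter elevations persisting to ~216 h.

## Cohort statistics

* 2×2 diagnostic accuracy uses each patient's *earliest* session inside
  [0, 24) h (strict > 33.4 µs abnormality); odds ratio by cross-product
  with Haldane–Anscombe +0.5 on all cells when any cell is zero; Woolf
  logit 95% CI; two-sided Fisher exact p (exact, and the test the table
  sizes warrant; the source analysis does not name its test).
* Window comparisons take one session per patient per window (earliest;
  avoids pseudo-replication), windows closed-left/open-right. Mann–Whitney
  is exact by full enumeration over pooled midranks when both n ≤ 8
  (two-sided p = P(|U − n₁n₂/2| ≥ observed); correct under ties);
  otherwise a normal approximation with tie-corrected variance, 0.5
  continuity correction and a fourth-cumulant Edgeworth term using the
  exact no-tie excess kurtosis of U,
  κ₄/σ⁴ = −(6/5)(n₁² + n₂² + n₁n₂ + n₁ + n₂)/(n₁n₂(n+1)), which keeps the
  approximation within ~10⁻³ of enumeration even at n₁ = n₂ = 8. Windows
  with an empty group contribute p = 1 so the correction's m stays at the
  number of windows.
* The step-down procedure implements the published description verbatim
  (smallest p at α/m, next at α/(m−1), …, stop at first failure). That
  rule is Holm's step-down procedure, although the description labels it
  Hochberg; the tests cross-check it against an independent step-through
  and statsmodels' Holm implementation.
* Time to normalization is the first session at which the patient's median
  jitter was normal; patients never normal (deaths, censored follow-up) are
  excluded from the extubation correlation and counted as censored.
* The AChE group comparison reuses the rank-sum test on the simulated
  covariate.

## Reported-value discrepancies

The observed 2×2 counts (24/4, 16/22) imply sensitivity 85.71% (≈ 86),
specificity 57.89%, OR = 528/64 = 8.25 and a Woolf CI of ~2.4–28.5;
published summaries of the same counts give OR = 8.9 (2.4–29.6), and quote
86.21% sensitivity elsewhere (which would require 25/29). These cannot be
reproduced from the printed counts; the package reports what its inputs
imply and pins no result to the irreproducible values.

## What the synthetic data does not emulate

Electrode repositioning and stimulus-threshold search (stimulation is
assumed supra-threshold; threshold-hovering exists only as an artifact
class), the velocity-recovery function (irrelevant at a constant 10/s),
blink-reflex/F-wave contamination, non-stationary noise and movement
artifact, real SFAP morphology variation beyond the parameterized
template, day-to-day electrode-site variability within a patient, and any
treatment effects (atropine/oximes). Passing tests therefore demonstrate
correctness of the measurement and inference chain under the stated
generative model — not performance on recordings from a clinical EMG
system, whose native file formats are also out of scope (CSV + JSON
sidecars are the interchange format).

## Problem sizes and runtime

Tests and the acceptance script run on one CPU in minutes: estimator
recovery uses 500 fibres × 100 sweeps per condition; the confusion matrix
200 fibres per class; the window-pattern study 50 cohorts of 120 patients;
the correlation preset 200 cohorts of 60 patients. These sizes hold the
Monte-Carlo error on each checked quantity well inside its test tolerance.
All randomness flows from explicit seeds through `numpy.random.SeedSequence`
substreams keyed by entity indices, so cohorts are bit-reproducible and
adding a patient or fibre never perturbs the others.
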