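# Methods

This note documents the models behind `crowdaudiometry`, the parameters
that matter, what the synthetic cohort does and does not emulate, and
the numerical choices made where the design was genuinely open.

## The staircase and the virtual listener

The simulated self-test reproduces the decision structure of a mobile
pure-tone screening app. Stimulus levels live on a 5 dB grid between
−10 and 100 dB HL. The search starts at 40 dB HL, descends one step
after every "I can hear", ascends one step after every "I can't hear",
and confirms the threshold at the first ascending reversal — the lowest
level answered "hear" with a "not hear" immediately below — or at the
floor/ceiling. A hard cap (200 presses) guards against non-terminating
parameterizations. With a deterministic listener this procedure returns
the true threshold rounded **up** to the grid, which the test suite
verifies by exhaustive sweep; with response noise the
confirm-on-first-reversal rule is slightly optimistic (it can lock onto
a lucky "hear" a step early), one of the measurement biases the package
is designed to surface.

The listener answers via

P(hear) = λ/2 + (1 − λ) · σ((L − θ_eff) / s)

- `psychometric_slope` *s* (dB): width of the hear/not-hear transition.
  Default 2 dB; *s* = 0 is the deterministic step-function limit.
- `lapse_rate` λ: probability of a random response per trial. Default
  0.02.
- `confusion_prob` *c*: probability per trial of responding "hear" to
  the contralateral masker rather than the tone, applied whenever the
  masker is on. Default 0.02. This is modelled per trial, not per
  subject, as the simplest mechanism that concentrates spurious
  confirmations at 40–45 dB HL: the masker first switches on at the
  45 dB HL presentation, so a confused response there is immediately
  bracketed and confirmed.

Masking rule: no masker for tones at or below 40 dB HL, a 40 dB HL
masker above 40, raised to 60 dB HL above 60 ("exceeds" is strict:
a 40 dB HL tone emits no masker). Tone modulation (2 Hz, 100 % depth)
has no audibility consequence at the decision level modelled here and
is not represented.

### Ambient noise

Room noise masks soft test tones. The masked floor is piecewise linear
in LAeq: zero at or below the 35 dB(A) reference, rising at
0.32 dB per dB(A) above it, so a normal-hearing listener in a
60 dB(A) room measures ≈ 8 dB HL. The floor applies only to acoustic
levels at or below a 40 dB HL soft-tone ceiling: loud tones are not
masked by ordinary room noise, so the adjustment derived from it is an
upper bound for hearing-impaired listeners. The slope and reference are
`StaircaseConfig` fields.

### Device models and calibration

A device model's headphones deviate from nominal output by a
per-frequency `true_offset` (generator default: Gaussian, SD 4 dB
across models). The biological calibration coefficient is the mean
deviation of raw thresholds measured by normal-hearing subjects from
the expected normal threshold (0 dB HL by definition of the HL scale),
with at least 16 measurements required per model; its standard error is
SD/√n. In the simulator the acoustic level reaching the ear is
`nominal − true_offset + coefficient`, so a perfectly calibrated device
cancels exactly and a residual calibration error of δ dB shifts every
recorded threshold by δ (up to grid rounding) — records themselves stay
on the 5 dB grid, as the app can only emit grid levels. The post-hoc
model adjustment subtracts each model's centered mean threshold
(models with < 2 records pass through), conserving the grand mean to
float precision.

## The synthetic cohort

The generator emulates the statistical structure of a crowdsourced
screening dataset; defaults are chosen to be realistic for that
setting:

- **Age**: decade-binned draw matching the observed age mix of
  crowdsourced screening users (peak at 30–49, long thin tail to 90);
  an entered age is present on 7 % of records, with a 2 % chance of a
  second conflicting entry to exercise the elimination rule.
- **Thresholds**: an ISO 7029-style stand-in — mean threshold
  `base(f) + α(f)·(age − 18)²` with α rising from 0.003 (250 Hz) to
  0.022 (8 kHz) dB/yr², a person-level Gaussian effect (SD 8 dB) shared
  across frequencies, independent per-ear effects (SD 3 dB), and
  residual noise (SD 5 dB), clamped to [−10, 100] dB HL and quantized
  to the grid. The closed-form clamped-Gaussian mean serves as the
  Monte-Carlo oracle in tests. True thresholds are quantized at
  generation so that the deterministic end-to-end null (pipeline
  prevalence = oracle prevalence from true thresholds) holds exactly.
- **Country prevalence**: each listener is drawn impaired with the
  country's target probability and shifted in 5 dB steps (plus a
  geometric margin, mean ≈ 2.9 steps, to avoid pile-up at the cutoff)
  until the better-ear PTA4 is on the required side of 25 dB HL. The
  configured target is therefore the exact generating prevalence,
  recoverable from true thresholds up to binomial noise. Targets are
  enforced marginally, independent of age.
- **Devices and repeats**: ~1 model per 20 devices; tests per device
  `1 + Poisson(mean − 1)` with default mean 3.1; 12.5 % of tests run
  with disconnected headphones; 0.7 % are incomplete.
- **Durations**: per-press time is lognormal (median ≈ 2 s,
  σ_log 0.35), scaled by a per-listener speed factor (σ_log 0.25), and
  the per-frequency duration is presses × per-press time summed over
  both ears. A rushed subpopulation (default 60 % of tests, matching
  the high rejection rates seen in unsupervised screening) replaces the
  speed factor with a short lognormal (median ≈ 0.06, i.e. ~0.3 s per
  press). The two populations must be well separated in log-duration
  for the QC mixture to be identifiable; since duration is also
  proportional to press count (which shrinks as the threshold
  approaches the 40 dB HL start level), duration-based exclusion is
  mildly correlated with hearing status — a genuine property of
  timed staircases that the pipeline inherits.
- **Ambient noise**: LAeq ~ N(45, 10) dB(A) clipped to [25, 85];
  monitoring consent on 25.8 % of tests; monitored users sit in rooms
  3 dB(A) quieter by default (self-selection), which generates the
  monitored-vs-unmonitored group difference the noise analysis
  estimates.

What the generator does **not** emulate: real headphone frequency
response curves, test-retest learning effects, within-person threshold
drift, non-random missingness (age or monitoring correlated with
hearing), geolocation error, or fraudulent/bot records beyond the
rushed subpopulation. Passing tests therefore demonstrate that the
pipeline recovers what this generative structure encodes, not that real
crowdsourced data satisfy these assumptions.

## QC cascade

Stages run in fixed order — completeness (14 thresholds), headphone
status, time criterion (minimum per-frequency duration below
threshold), one-per-device — and each record is attributed to its first
failing stage, so the flow counts always sum to the input size.
Reading "the measurement at any frequency was carried out quicker than
the threshold" as *minimum per-frequency duration < threshold* is
equivalent. Deduplication keeps the latest surviving record with a
consolidated (single-valued) age if one exists, else the latest
overall; timestamp ties break by record id.

The time criterion is the 0.99 quantile of the short-duration
component: log durations are fitted with a two-component Gaussian
mixture (EM, fixed seed, 3 restarts) and the component with the smaller
mean is read as the rushed population. A single-lognormal mode
(`mixture=False`, plain MLE) is available where the data are known to
be homogeneous. Degenerate inputs (zero variance, non-positive
durations, n < 30) are rejected.

## Analysis

- **Classification**: PTA4 (mean of 0.5/1/2/4 kHz) strictly above
  25 dB HL in the better (lower-PTA4) ear.
- **Sample-size gate**: ⌊((z_{1−α/2} + z_power)·σ/δ)²⌋, floored rather
  than ceiled because the floor variant reproduces the reference value
  90 at (σ 17 dB, δ 5 dB, α .05, power .8); clamped to ≥ 1.
- **Bootstrap**: percentile method, default 2000 resamples, seeded;
  degenerate (constant) inputs return a point interval.
- **KS comparison**: standard two-sample Kolmogorov–Smirnov test
  (asymptotic p); in this pipeline non-rejection is read, loosely, as
  subgroup equivalence — the test cannot prove equivalence, it can only
  fail to find a difference.
- **Noise effect**: monitored records are binned in 5 dB(A) LAeq bins
  above the ≤ 35 dB(A) reference bin; per-bin mean-threshold deltas vs
  the reference give the adjustment (cohort-weighted mean, bootstrap
  SE over monitored records). The monitored-minus-unmonitored mean
  difference (two-sample SE) is added; means add and SEs combine in
  quadrature by construction. The prevalence reduction subtracts the
  overall effect from every threshold and reclassifies, reported in
  percentage points of global prevalence.
- **Country difference**: absolute = p_high − p_low; relative =
  absolute/p_high × 100 (the headline convention; the conventional
  p_low base is available behind a flag).
- **Masking-bias score**: observed minus predicted mass in the 40 and
  45 dB HL bins, clamped at zero. The null histogram is fitted by a
  *truncated* binned lognormal MLE — the likelihood is renormalized
  over the non-spike bins — because a plain MLE on the remaining values
  is biased whenever genuine mass sits at 40–45 and produces spurious
  excess. Thresholds are shifted by max(15, −min + 2.5) dB onto
  positive support. If nearly everything sits in the spike bins the
  observed mass itself is returned (degenerate fit guarded).
- **Heterogeneity**: a chi-square test on the country × loss table is
  provided as a descriptive diagnostic. No multiple-testing correction
  is applied across country comparisons (a single global test plus
  pairwise CIs are reported).
- **Age curves**: decade groups 20–29 … 80–89; ages 18, 19 and 90 and
  missing/conflicting ages are excluded to keep equal decade ranges;
  both ears are pooled per frequency by default (better-ear medians via
  a flag); medians with percentile-bootstrap CIs.

## Numerical and scale choices

- All randomness flows through `numpy.random.Generator` seeded from
  config; pipeline reruns are byte-identical. Derived stage seeds are
  seed, seed+1, seed+2.
- Grid quantization uses round-half-to-even at construction; staircase
  outputs are grid values by construction. Grid validation is enforced
  at I/O (raw records must be on-grid) but not on in-memory records, so
  analytically adjusted thresholds (model centering, noise shifts)
  remain representable.
- CSV export writes floats with `%.17g` and reads with round-trip
  parsing so the flat format is lossless.
- The parameter-recovery test (50 replicate cohorts, 3 countries × 300
  tests, targets 10/20/35 %) runs with deterministic listeners, zero
  offsets, quiet rooms and a fixed 5 s time criterion; 1000 bootstrap
  resamples per interval are ample for a stable percentile CI at
  n ≈ 300. Other simulation tests use cohorts of 60–1500 devices,
  sizes at which their binomial tolerances are already decisive.

## Known limitations

- The staircase's confirm-at-first-reversal rule underestimates noisy
  listeners' thresholds slightly; combined with classification at a
  hard cutoff, psychometric noise inflates measured prevalence by a few
  percentage points relative to the generating truth under default
  (noisy) settings. This is deliberate behaviour of the simulator, not
  of the estimator: with deterministic listeners the pipeline is exact.
- Duration-based exclusion correlates with proximity of the threshold
  to the start level (fewer presses → shorter test), so aggressive time
  criteria can preferentially remove mildly impaired listeners.
- The ambient-noise floor is a deliberately simple piecewise-linear
  model anchored at one point; it ignores spectral masking detail.
- The biological calibration model treats within-model device
  variability as exchangeable noise; serial-level calibration is out of
  scope.
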