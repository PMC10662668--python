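# Methods

## What is being modeled

A tablet app screens preschool children (4–5 y) one ear at a time with
spondee words and six candidate pictures. The protocol starts at 40 dB HL in
the right ear, shows up to three picture sets per level, passes the level on
2 correct of 3, fails it on any 10 s timeout or once 2-of-3 becomes
unreachable, then descends 40 → 30 → 20 dB HL; the descent stops at the
first failed level, and the process repeats for the left ear. The lowest
passed level fixes the screened category with the childhood-screening
cutoffs (≤ 20 normal, > 20–≤ 40 mild, > 40 moderate). The package simulates
this protocol on virtual children, simulates the reference test
(conditioned play audiometry, 0.5/1/2/3/4 kHz pure tones), and computes the
agreement statistics a validation study would report.

## Response model

Probability of a correct picture choice at presentation level *x* against
ear threshold θ:

ψ(x) = γ + (1 − γ − λ) · logistic((x − θ)/σ)

- γ = 1/6, fixed by the 6-alternative task. Not a free parameter.
- λ (lapse rate), default 0.02: finger slips and attention lapses at clearly
  audible levels. σ (slope), default 4 dB: speech-in-quiet identification
  functions for single words are steep; 4 dB puts the 16→98% rise inside
  ~±10 dB. τ (timeout probability), default 0.01 per presentation,
  independent of level. These three are simulator priors for a cooperative
  preschooler — no behavioral estimates exist for this population, so they
  are explicit knobs meant for sensitivity analyses, not claims.
- The ear's scalar θ is the pure-tone average of its audiogram; cohort
  audiograms are flat by default so this is exact.
- σ = 0 is accepted as the deterministic step limit (correct iff x ≥ θ,
  ties audible), and `PsychometricParams.noiseless()` additionally sets
  γ = λ = τ = 0. This limit is what makes the exhaustive grid test of the
  engine possible; the tie convention mirrors the inclusive category
  boundaries.
- A timeout fails the whole level immediately rather than counting as one
  incorrect response; the protocol description treats "no answer in 10 s"
  as level failure, and the descent then continues from that failure (a
  first-set timeout does not abort the other levels or ear).

## Acoustics

Word recordings are RMS-equalized to a common target, then each (word,
level) pair carries a calibration coefficient — the gain that makes the
device's measured dBA peak match the reference audiometer through a 6cc
coupler. The simulator reduces the physical chain to that scalar (plus an
optional zero-mean residual error, default sd 0 dB, since no residual
calibration error is quantified per headphone).

Room noise enters through a deliberately transparent masking model:

effective level = nominal + cal_error − max(0, ambient − isolation − offset)

with the headphone's passive ambient isolation from its datasheet (TDH39
with earmuffs 30 dB, DT 770 PRO 20 dB, generic earmuff headphones 30 dB)
and a masking offset of 10 dB, i.e. residual noise more than 10 dB below
the signal does not mask. This is a threshold-elevation approximation
chosen for inspectability over psychoacoustic fidelity (no critical-band or
frequency-dependent treatment). Screening is assumed to happen in a quiet
hospital room at 35 dBA ambient (no figure is published for the setting;
35 dBA is a typical measured level for such rooms). Under these defaults
the TDH39 and generic cups are unaffected while the DT 770 PRO loses 5 dB
of effective level — a plausible, visible penalty for the weaker seal.

## Cohort generator

The generative unit is the child: bilaterally normal with probability 0.70,
unilateral loss 0.21, bilateral loss 0.09 — the composition observed in the
44-child validation cohort (31/9/4). Loss ears are moderate with
probability 0.2 (the mild/moderate ear split is not published; 0.2 loosely
matches the few moderate ears recoverable from the printed tables and is
configurable). Thresholds: normal ears ~ Normal(10, 5) truncated to
[−10, 20]; mild ~ Uniform(25, 40); moderate ~ Uniform(45, 70) dB HL, flat
across frequency by default (optional per-frequency jitter). Flat
audiograms keep the true category unambiguous, matching how a screening
study reports one level per ear; they do not emulate sloping or notched
configurations, so passing tests say nothing about frequency-dependent
losses.

The simulated reference test adds per-frequency Normal(0, 2.5 dB)
measurement noise (a conservative test–retest figure for behavioral
audiometry; configurable, 0 disables), quantizes to the audiometer's 5 dB
steps, and classifies the 5-frequency pure-tone average. An option
classifies by worst single frequency instead, for sensitivity analyses;
the PTA rule is the default because the reference test measures exactly
those five frequencies and summaries are reported against the PTA.

## Durations

Per presentation the app draws a log-normal response time (median 4 s,
log-sd 0.5) truncated at the 10 s timeout, plus 2 s of inter-trial
overhead; a normal-hearing ear then takes ~40 s and a child ~80 s for both
ears, consistent with the reported app test times (means ~80–91 s, range
46–150 s). The reference test draws one log-normal per child (median
560 s, log-sd 0.25, split evenly between ears), consistent with the
reported 421–1152 s range. These models exist only so duration comparisons
(paired *t*) have realistic inputs; they carry no claim about real response
latencies.

## Statistics

- κ = (p₀ − pₑ)/(1 − pₑ); the z test of κ = 0 uses the Fleiss large-sample
  null standard error SE₀ = √(pₑ + pₑ² − Σᵢ pᵢ₊p₊ᵢ(pᵢ₊ + p₊ᵢ)) /
  ((1 − pₑ)√N), two-sided — the form the major packages use, and the one
  that reproduces the published p-values. pₑ = 1 (single-category tables)
  is signaled, not NaN-ed.
- Sensitivity/specificity CIs are exact Clopper–Pearson via beta quantiles,
  with closed endpoints at x = 0 and x = n. McNemar is the exact two-sided
  binomial test on discordant pairs (p = 1 with none).
- `reconstruct_from_summaries` searches all integer (x, m) consistent with
  the margins and keeps those whose sensitivity and CI round — half-up, at
  each printed value's own decimal precision — to the printed numbers.
  Half-up matches how results tables are typically rounded. No solution and
  multiple solutions are distinct, loud errors; the multiple-solution error
  carries the candidate tables.
- One-vs-rest dichotomization per category (normal/mild/moderate) mirrors
  the three-row structure of published agreement tables. The mild and
  normal rows of the motivating study are not exactly expressible as k/88
  under any dichotomy tried, so reconstruction-based checks target the
  moderate rows, whose tables are uniquely recoverable; mild/normal
  behavior is covered by property-based tests instead.
- Percentages are carried on the 0–100 scale throughout.

## Problem sizes and numerical choices

The replicated-study check runs 200 studies of 44 children with all three
headphones (a few seconds total); prevalence recovery uses a 10,000-child
cohort with a χ² goodness-of-fit at α = 0.01; the κ implementation is
verified against an explicit N²-pairing enumeration oracle on 1,000 random
tables, and Clopper–Pearson endpoints against bisection of raw binomial
tail sums for every x, n ≤ 30. The deterministic-screening property is
exhaustive over integer thresholds 0–80 dB HL. RNG streams are
`numpy.random.Generator` spawns: one per child, then one per test, so
per-child test order (randomized, logged) consumes randomness
reproducibly; identical seeds give byte-identical report files.

## Known limitations

- No frequency-dependent transducer response, distortion synthesis, or real
  audio playback; word identity does not affect difficulty by default.
- The masking model is a scalar threshold-elevation rule; it will not
  reproduce spectral masking phenomena.
- Behavior parameters are assumptions; conclusions about real children
  require varying them.
- A paired *t* on durations is undefined for exactly constant differences
  (zero variance); the implementation signals this rather than returning a
  statistic.
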