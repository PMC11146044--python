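# Methods

`okndecode` implements the analysis chain of a bimodal multistability
experiment in which a participant reports a bistable *auditory* percept
(ABA_ tone streaming heard as one integrated stream or two segregated
streams) while their bistable *visual* percept (pattern-component rivalry:
a coherent plaid vs. separate gratings) is read out without any report,
from the optokinetic nystagmus (OKN) of the tracked eye.  The core
question the chain answers is whether the two percepts flip together on a
moment-by-moment basis.

## Measurement model

The OKN slow phase tracks the perceived motion.  The plaid (integrated)
percept has a larger horizontal motion component than the gratings
(segregated), so the slow-phase horizontal velocity — and the duration and
extent of the resetting fast phases — carry the visual percept.  Three
per-sample signals are extracted from the 1000-Hz horizontal gaze trace:

1. **smoothed slow-phase velocity** (deg/s): sample-to-sample differences
   computed only where two consecutive samples are both slow-phase and
   valid, then averaged over a trailing 1-s window;
2. **fast-phase-direction run length** (samples): for each sample, the
   length of the maximal run of consecutive samples whose local
   displacement points in the fast-phase direction;
3. **fast-phase-direction run extent** (deg): the distance covered by that
   run; both run series are smoothed with the same trailing 1-s mean.

A linear soft-margin SVM decodes the percept from a 63-dimensional feature
vector per 100-Hz timepoint: the three signals sampled at 21 lags from
−2.0 s to 0 s in 100-ms steps.  All smoothing is trailing (causal), so no
feature uses samples after its timepoint — the construction would work in
real time.

Decoding and consistency are always scored as **class-adjusted (balanced)
accuracy**: per-percept accuracies are computed first and averaged with
equal weight, so chance is 50% no matter how asymmetric the reported
percepts are.

## Segmentation choices

The fast/slow segmentation is a velocity-threshold saccade detector:
samples whose Savitzky–Golay derivative (10-ms window, polynomial order 2)
exceeds 22 deg/s for at least 4 ms are fast; events closer than 20 ms are
merged.  The threshold sits two orders of magnitude above the ~1.9 deg/s
slow-phase drift and well below the ~80 deg/s fast-phase speed, so the
labels are insensitive to its exact value.  Runs of missing samples
(blinks) are padded by 50 ms on each side; padded samples are excluded
from all statistics, break displacement runs, and are never interpolated.

The run-direction sign is taken from a 20-ms Savitzky–Golay velocity
rather than raw sample differences.  At 1000 Hz the per-sample slow-phase
drift (~0.002 deg) is far below position noise of even a good video
tracker (~0.01 deg), so raw displacement signs are near coin flips during
slow phases and would shred the run statistics; the 20-ms local regression
restores the intended noise insensitivity (verified by a jitter-robustness
test).  Setting `sign_smooth_ms=0` recovers the literal raw-difference
definition.

## Decoder training and model selection

One unimodal visual block trains 11 SVMs over the cost grid (0.0001,
0.0005, 0.001, 0.005, 0.01, 0.1, 1, 2, 5, 10, 100); a second block picks
the cost with the highest balanced accuracy (ties break toward the
smallest cost, i.e. stronger regularization); the third block measures the
retained model's accuracy.  All 3! = 6 ordered role assignments are run
and the six models are treated as exchangeable.  Features are standardized
by training-block statistics (the three variables have incommensurate
units and linear SVMs are scale-sensitive); zero-variance columns pass
through.  Training rows with no exclusive report, or whose lag window
leaves the block or touches missing data, are dropped rather than
imputed.  The implementation uses liblinear (primal, squared hinge,
class weights inversely proportional to class frequency so training
matches the balanced evaluation objective); it is deterministic given
fixed inputs.

## Consistency and bounds

In bimodal blocks only the auditory percept is reported.  The six visual
decoders are applied to each of the eight bimodal blocks and scored
against the auditory report as if it labeled the visual percept; the
6 × 8 balanced accuracies are averaged into the participant's
**consistency**.  Cells whose auditory labels contain only one percept
are undefined and excluded from the mean.

Consistency cannot reach 100% (or 0%) when the segregated-percept
proportions differ between modalities.  With `a` and `v` the auditory and
visual segregated proportions, the extreme joint distributions with those
marginals give

    theo_max = 1/2 [ min(a,v)/a + min(1−a,1−v)/(1−a) ]
    theo_min = 1/2 [ max(0,a+v−1)/a + max(0,1−a−v)/(1−a) ]

(certified against a linear-programming oracle over all joint occupancy
tables to 1e-9 on a 20 × 20 grid; the certification is part of the test
suite and a failing certification blocks release).  Imperfect visual
decoding accuracy `d` and auditory reporting accuracy `r` attenuate the
observable consistency further: under error independence a true match is
observed as a match with probability `q = d·r + (1−d)(1−r)`, and each
per-class true-match proportion `m` at a theoretical extreme becomes
`m·q + (1−m)(1−q)` before averaging, giving `exp_max` and `exp_min`.
For `d, r ≥ 0.5` the bounds nest: `theo_min ≤ exp_min ≤ 0.5 ≤ exp_max ≤
theo_max`.

The pipeline reports the plug-in estimates the experimental procedure
affords: `a` from the auditory reports of the bimodal blocks, `v` from the
unimodal visual reports, `d` from the unimodal evaluation accuracy, `r`
from the auditory catch-trial hit rate.  These are *estimates*: `r` is
penalized by the report latency (the schedule is unlagged, the report is
not) and `v` comes from different blocks than the consistency.  On
synthetic sessions with strong coupling the consistency comparison — which
is latency-matched on both sides, because the decoder learns the report
timing convention — can exceed the plug-in `exp_max`.  The simulator
therefore also exposes *realized* quantities (latent occupancies of the
bimodal blocks; balanced accuracy of the decoded and reported series
against the lag-shifted latent states), and the containment property is
validated against those; the plug-in bounds are validated as a bracket of
the group mean in the weak-to-moderate coupling regime.  This distinction
is a substantive caveat for the bounds' independence assumption whenever
observed consistency approaches the expected maximum.

## Synthetic sessions

The generator emulates a two-day paradigm's second day: 13 blocks
(3 unimodal visual, 2 unimodal auditory, 8 bimodal), each 180 s
multistable plus a 30-s disambiguated tail in which four 7.5-s segments
alternate the suggested percept, each percept occurring twice.  Reports
are collected for the visual modality in unimodal visual blocks and for
the auditory modality otherwise.

**Percept dynamics.** Dominance phases are gamma-distributed with shape 3
(right-skewed unimodal durations typical of multistability) and mean 9 s,
whose distribution median ≈ 8 s matches the phase durations such stimuli
elicit.  Cross-modal coupling uses a shared alternating-renewal process
plus independent per-modality agree/disagree renewal processes with
stationary disagree probability δ = (1 − κ)/2; during disagreement a
modality shows the common state flipped.  The stationary match probability
is (1 + κ²)/2 — 1 at κ = 1, 1/2 (independence) at κ = 0.  Because both
the common switches and the disagreement transitions flip a modality's
state, the common process is slowed to mean 9/κ s and disagreement phases
get mean 9 s, keeping each modality's switch rate ≈ 1/9 s⁻¹ at every κ.
Segregated occupancy targets are met by inverting the flip map
(`pi_c = (pi − δ)/(1 − 2δ)`) applied to the mean of the two modality
targets; occupancy is exact when the targets agree, and is pinned to 0.5
at κ = 0 where the flip erases asymmetry.  Differing per-modality targets
are honored only approximately — a pure flip is required to keep the
match probability exact.

**Reports.** The latent trace is delayed by a 0.4-s report latency; whole
phases are mislabeled independently with probability `eps_report`
(defaults 0.1, matching ~85–90% catch-trial performance); no-report gaps
with total fraction `gamma_gap = 0.03` (≈97% exclusive-report coverage)
are inserted around switches, where button releases occur in practice.

**OKN.** Sawtooth gaze: slow drift at 1.9 deg/s (integrated) or 0.5 deg/s
(segregated) — values are simulator choices, as percept-conditional
slow-phase velocities are not published for this stimulus — with a fast
phase at 80 deg/s triggered at 2 deg eccentricity, of mean duration 60 ms
(integrated) or 35 ms (segregated), so duration and extent are larger
during integration.  White position noise (SD 0.01 deg) and Poisson
blinks (3/min, mean 150 ms, replaced by missing samples) complete the
trace.  Disambiguated tails force the latent state to the schedule with a
300-ms transition lag.

**What the generator does not emulate:** smooth pursuit intrusions,
drift/calibration error, pupil artifacts, vertical gaze, piecemeal or
mixed percepts, serial dependencies between blocks, and learning effects.
Passing tests therefore certify the analysis chain — segmentation,
features, model selection, scoring, bounds — under a faithful generative
model of the *signal structure*, not performance on any real recording.

## Numerical and design choices

- Sliding averages are trailing; whether the original analyses used
  centered or trailing windows is not documented, and the causal choice is
  the one compatible with the lag structure (exposed as a config switch in
  the preprocessor, with only the causal option implemented).
- Decoding and consistency are scored on the 180-s multistable part only;
  tails feed the hit rates.
- Balanced accuracy raises an error when a class is absent (zero
  denominator); consistency cells with single-class auditory labels are
  excluded from the participant mean rather than imputed.
- Cost-selection uses balanced accuracy on the optimization block, for
  consistency with the evaluation metric.
- Inclusion criteria: visual and auditory unimodal hit rates ≥ 70% and
  mean unimodal decoding accuracy ≥ 70%, each flagged separately.
- Group statistics are two-tailed one-sample/paired t-tests and Pearson
  correlations, unadjusted for multiple testing.
- A single master seed expands into per-participant (`spawn_key=(p,)`)
  and per-block (`(p, block, stream)`) seed-sequence children, so any
  block regenerates in isolation and identical configs reproduce outputs
  byte-identically.

## Problem sizes

Unit and property tests run on seconds-to-minutes of synthetic signal.
The end-to-end recovery suite analyzes eight fixed-seed participants at
each coupling level κ ∈ {0, 0.3, 0.6, 0.9} (full 13-block sessions,
1000-Hz gaze, the package's default scale for a desk-size validation run);
participant seeds are shared across κ so coupling-level contrasts use
common random numbers.

## Known limitations

- The closed-form bounds assume decode/report error independence; the
  synthetic sessions show measurable violations near κ = 1 (shared report
  latency), and real data may violate it through attention fluctuations
  that degrade decoding and reporting together.
- The simulator cannot represent "both buttons pressed"; readers of real
  report data must map such periods to the no-report state.
- `LinearSVC` (squared hinge, penalized intercept) stands in for the
  classical SMO-based libSVM linear kernel; decision boundaries agree for
  well-separated data but regularization paths differ in detail.
- Per-modality occupancy targets interact with coupling (exact only when
  equal across modalities; pinned to 0.5 at κ = 0).
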