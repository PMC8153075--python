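# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `ternuseye`. It is written for users who want to judge
what the package's validation on synthetic data does — and does not —
establish about recorded eye-tracking data.

## Experiment designs

All designs share the trial timeline: a central fixation of 3–5 s
(uniform), a 200-ms peripheral fixation at ±9.7°, 100 ms blank, 200 ms
central refixation, 300 ms blank, then the two 30-ms Ternus frames
separated by one of seven ISIs (50–230 ms in 30-ms steps, so SOA =
ISI + 30 ∈ {80…260} ms), 300 ms blank, and a response probe. Beeps, when
present, are synchronous with the frames.

* **E1** (fully randomized): 7 SOA × 2 sound × 24 trials = 336, with
  left/right motion balanced 12/12 in every cell, in two blocks of 168.
* **E2** (sound blocked): four blocks of 84 trials, two per sound
  condition in an alternating (2-condition Latin square) order; 12 trials
  per SOA per block, 6 left / 6 right.
* **E3** (SOA blocked): one block per SOA. The source design is
  arithmetically ambiguous, so the default is seven blocks of 24 trials
  (12 sound / 12 baseline, balanced directions; 168 total); the trials
  per block are configurable (`e3_trials_per_block`).
* **E4** (localization control): the E1 schedule without visual frames.
  Every E4 trial's timeline carries `beep1`/`beep2` anchors at the
  nominal frame times so that epoching and gaze-window extraction remain
  uniform; the beeps are audible only on sound trials.

Designs are pure functions of (experiment, seed): the permutation and the
per-trial fixation durations are both driven by the seed.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated. Its defaults are chosen once: behavioral parameters equal the
pooled condition means the paradigm is known to produce (PSE 180.1 ms
baseline / 100.2 ms sound; JND 37.9 / 42.6 ms), and the oculomotor,
pupil and reaction-time process parameters are the package's own choices
of realistic values, listed below with their rationale.

**Behavior.** Group-motion reports are Bernoulli draws from the logistic
with scale s = JND/ln 3 per sound condition. E4 reaction times are
truncated normal (mean 537 ms sound / 603 ms baseline, SD 110 ms, lower
bound 150 ms) — simple, positive, and on the scale of reported means.

**Gaze traces** (500 Hz) are the sum of:

* *Fixational drift*: an Ornstein–Uhlenbeck velocity process (stationary
  SD 0.10 °/s, time constant 100 ms) integrated to position, plus white
  measurement noise of 0.001° SD. These values put the session's
  median-based velocity SD near 0.14 °/s, i.e. a detection threshold
  λσ ≈ 1.1 °/s — far below microsaccadic peak velocities, as in clean
  video-oculography.
* *Microsaccades*: an inhomogeneous point process (thinning) with base
  rate 1.5 Hz — a typical fixational rate — multiplied by a smooth gain:
  a Gaussian inhibition dip after each frame (depth 0.9, latency 120 ms,
  width 80 ms), a rebound overshoot after the second frame (gain 0.8,
  latency 450 ms, width 150 ms), and, on sound trials only, an extra
  late suppression centered 860 ms after frame 1 (depth 0.6, width
  130 ms). The late term is what makes the sound condition's rate lower
  in the 750–1000 ms window — the qualitative oculomotor-inhibition
  pattern the pipeline is expected to recover. A 20-ms minimum
  offset-to-onset gap is enforced (earlier event wins).
* *Waveforms*: each event is a minimum-jerk displacement ramp. Amplitude
  is lognormal (median 0.35°, log-SD 0.4, clipped to [0.12, 1.5]°, i.e.
  microsaccadic range); peak velocity follows the main sequence,
  V = slope · A · ε with slope 100 s⁻¹ and multiplicative lognormal noise
  (log-SD 0.22), which fixes the duration D = 1.875·A/V (8–60 ms) because
  a minimum-jerk ramp peaks at 1.875·A/D. Directions are horizontally
  biased (±15°) and drawn toward the fixation point when the eye has
  drifted beyond 0.2°, keeping traces bounded. The bookkept onset is
  snapped to the sample grid where the ramp actually starts.

**Pupil traces** are a session baseline (3000 au) plus a gamma-shaped
impulse response h(t) = (t/tp)ⁿ·exp(n(1−t/tp)) per stimulus event
(tp = 600 ms, n = 6; each visual frame contributes 150 au, each beep an
additional 120 au on sound trials), white noise (SD 30 au), and Poisson
blinks (0.1 Hz, ~120 ms) stored as missing samples. The time-to-peak is
on the fast side of published pupil response functions so that the
sound/baseline difference emerges within the 1-s epoch, as the paradigm's
pupil effect does.

**What the generator does not emulate**: saccadic intrusions larger than
the microsaccade range, square-wave jerks, pupil foreshortening artifacts
or arousal drifts across a session, inter-subject variability in
psychometric or oculomotor parameters (all virtual subjects share the
generating parameters; only their noise realizations differ), and any
dependence of microsaccade statistics on SOA. Passing tests therefore
establish the *correctness and calibration of the analysis code* under
realistic signal and noise scales — not that real data will show these
effects.

## Analysis pipeline

**Sample format.** Tab-separated text with `#` header lines
(session/trial ids, sampling rate, column order), one row per 2-ms
sample; missing pupil is `NA`. Positions are serialized at full float
precision so read∘write is an exact inverse; times carry one decimal.

**Blinks** are maximal runs of missing or non-positive pupil samples,
padded ±50 ms (the criterion is the package's own; sources rarely state
one), with overlapping padded runs merged.

**Gaze duration.** The "gaze" is the single fixation spanning the whole
presentation window [frame1 onset, frame2 offset). Any supra-threshold
velocity excursion (a detection *candidate*, before the duration filter —
so ordinary saccades also count) or blink breaks a fixation. Trials with
no spanning fixation, or with the response registered inside the gaze,
are flagged invalid with the corresponding reason. E4 trials span
[beep1, beep2 + 30 ms).

**Detection.** The 5-sample velocity estimator
v[n] = (x[n+2]+x[n+1]−x[n−1]−x[n−2])/(6Δt) is exact for linear signals
and suppresses sample noise. σ is computed per session (all trials
pooled), horizontal component only, as specified by the median-based
formula; the implementation notes explicitly that this estimator is *not*
translation invariant (an all-positive velocity sample is degenerate) —
it presumes velocities centered near zero, which fixation guarantees.
Sessions with σ < 10⁻⁶ °/s are rejected as degenerate. Candidates need
≥ ⌈3 ms/Δt⌉ = 2 consecutive supra-threshold samples; the duration filter
(3–110 ms) and the 20-ms minimum interval to the previous *kept* event
(offset-to-onset; onset-to-onset selectable) run in one left-to-right
pass, which makes the filter idempotent and its output pairwise
separated. The horizontal-only criterion follows the source convention;
a 2-D elliptic criterion is available behind `use_elliptic`.

**Amplitude/peak velocity.** Amplitude is the distance between the mean
gaze position of the two samples before onset and the two after offset
(robust to single-sample noise); peak velocity is the maximum 2-D speed
inside the event; edge events are flagged and use available samples.

**Rate curves.** Onsets only enter the raster (mass conservation is then
exact under the unit-sum kernel). The raw rate is trials-mean ×
sampling rate (events/s); "normalized by the number of trials and the
sampling rate" is read as divide-by-trials, multiply-by-rate — the
alternative double division has units of events/trial/sample, which is
not a rate. The kernel is truncated at 200 ms (10 time constants) and
renormalized; convolution treats pre-window rate as zero, so the first
~200 ms of a window carry an edge ramp that analyses must (and here do)
avoid by locking windows at −500 ms. The epoch default is
[−500, +1000) ms.

**Pupil preprocessing** interpolates only flagged/missing samples
(valid samples are never touched; leading/trailing gaps extend the
nearest valid value), z-scores per session ("variance normalization" read
as division by SD), and baseline-corrects by the half-open [−100, 0) ms
mean so the frame-onset sample is excluded. Averages are two-level with
SE across participants, matching how such data are reported.

**Cluster statistics.** The cluster-forming threshold is the two-tailed
t critical value at α (df = n−1); the cluster statistic is the mass
(sum of t); the null is the maximum |mass| over per-participant sign
flips of the paired differences (exact exchangeability under the paired
null); p = (1 + #{null ≥ |mass|})/(N + 1), never zero. Zero-variance time
points get t = 0 with a warning. The max-statistic construction controls
the familywise error across time, verified empirically in the acceptance
suite (200 null datasets × 1000 flips, 17 participants). Maxsum (not
maxsize) and the pointwise-critical-value threshold are the cited
method's defaults; both were genuinely open choices.

**Psychometric fitting** is binomial maximum likelihood (well defined at
0/1 proportions, unlike least squares), two parameters only (no lapse or
guess rates), optimized over (μ, log s) by Nelder–Mead from a
deterministic logit-linearized least-squares start; fits are therefore
reproducible bit-for-bit. Degenerate data (all identical proportions,
all 0s, all 1s) and scale blow-ups (s > 50 × the SOA span) are flagged
non-converged with NaN estimates; PSE/JND accessors raise on
non-converged fits. A PSE outside the tested 80–260 ms range is reported
but flagged `extrapolated`, never clipped.

**Pipeline.** Stages run simulate/load → detect → gaze → rates → pupil →
psychometrics → cluster statistics; each writes a CSV/JSON artifact when
an output directory is set, and `report.json` embeds the config snapshot
(minus the output path) and all seeds, making a rerun byte-identical.
Stage outputs are recomputed on every run; there is no caching layer.
Errors carry the stage name and the offending session/trial.

## Problem sizes used in the shipped validation

The default analysis dataset is 6 virtual participants on the full
336-trial E1 design — enough events (~7000) for stable main-sequence and
cluster estimates while a full run stays in seconds. The familywise
error-rate suite uses 200 null datasets × 17 participants × 1000
sign-flip iterations; psychometric recovery uses 10,000 trials per SOA
level; the detector round-trip uses 300 trials (~1300 injected events).
Heavier replications (more subjects, 2000-trial round trips) change none
of the conclusions and can be run by adjusting the config.

## Known limitations

* The median-based SD formula is degenerate for velocity samples far from
  zero (see above); it is kept because it is the standard companion of
  the λσ detection criterion.
* The horizontal-only criterion misses near-vertical microsaccades by
  construction; the generator's horizontal direction bias mirrors human
  fixational statistics, but vertical-heavy data should enable the
  elliptic criterion.
* Rate curves within ~200 ms of the left window edge are biased low by
  kernel truncation; analyses use windows that start 500 ms before the
  lock event so the [0, 1000] ms region of interest is unaffected.
* The permutation p-value resolution is 1/(N+1); with 1000 iterations the
  smallest attainable p is ≈ 0.001.
* Single-session inference (one participant) is out of scope: the cluster
  test and averages are across-participant procedures.
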