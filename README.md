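# ternuseye

Eye-metric analysis of audiovisual apparent motion: a tested, reusable
pipeline for studying how brief sounds reorganize the perception of a
two-frame **Ternus display** — the *crossmodal freezing effect* — through
microsaccades, pupil dilation, and psychophysics.

When the two Ternus frames are paired with clicks/beeps, observers report
the "group motion" percept more often: the sound makes the frames more
distinct, as if the inter-frame interval were longer. This package
implements the complete eye-movement and behavioral analysis for that
paradigm, together with a synthetic-data generator that emulates the
experiments, so every stage of the pipeline can be validated end to end
without any recorded data.

## What it computes

**Psychometrics.** The proportion of group-motion reports across the seven
stimulus onset asynchronies (SOA = ISI + 30 ms frame duration; 80–260 ms)
is fitted by binomial maximum likelihood with a two-parameter logistic
P(SOA) = 1 / (1 + exp(−(SOA − μ)/s)). The **PSE** (point of subjective
equality) is μ; the **JND** is half the 25–75% span, analytically s·ln 3.

**Microsaccade detection.** Velocities come from the standard 5-sample
moving-window estimator; a sample is supra-threshold when |v_x| exceeds
λ = 8 times the median-based standard deviation
σ = √(median(v²) − median(v)²) of the session's horizontal velocities.
Events shorter than 3 ms, longer than 110 ms, or within 20 ms of the
previous kept event are discarded. Event amplitude and peak velocity obey
the saccadic **main sequence** (near-linear amplitude/peak-velocity
relation).

**Oculomotor inhibition (OMI).** Event onsets are binned per trial relative
to the first/second Ternus frame, normalized by trial count and sampling
rate to events/s, and smoothed with the causal kernel
ω(τ) = α²τ·exp(−ατ), α = 1/20 ms⁻¹ (peak at 20 ms, unit mass). Segment
means over S1–S4 (0–250 … 750–1000 ms) summarize the time course.

**Pupillometry.** Blinks are linearly interpolated, each session is
z-scored by its own mean/SD, epochs are locked to the first frame and
baseline-corrected by the mean over [−100, 0) ms, and condition averages
are two-level (trials → participant → grand mean).

**Statistics.** Paired sound-vs-baseline differences over time are tested
with a nonparametric **cluster-based permutation test** (pointwise paired
t, cluster-forming threshold at the two-tailed α = 0.05 critical value,
max-|mass| null from 1000 per-participant sign flips). A per-participant
delta-OMI (500–1000 ms) vs delta-group-motion Pearson correlation probes
the oculomotor–perceptual link.

**Synthesis.** `ternuseye.synth` generates the four experiment designs
(fully randomized E1; sound-blocked E2; SOA-blocked E3; frame-less
localization control E4), logistic behavior, gaze traces (drift +
inhomogeneous microsaccade point process with stimulus-locked inhibition,
sound-deepened late suppression, and main-sequence waveforms), and pupil
traces (gamma impulse responses, extra gain per beep, blinks).

## Worked example

```python
import ternuseye as te

cfg = te.PipelineConfig(experiments=["E1"], n_subjects=6, seed=0,
                        n_iterations=1000)
report = te.run_pipeline(cfg)

print(report.psychometrics.groupby("condition")[["pse_ms", "jnd_ms"]].mean())
print(report.n_events, report.main_sequence_r)
for c in report.cluster_results["ms_rate_frame1"].significant:
    print(c.start_ms, c.end_ms, c.sign, c.p_value)
```

Output of this exact run:

```
           pse_ms  jnd_ms
condition
baseline    178.2    36.9
sound        97.8    43.0
7292 0.913
726.0 1000.0 -1 0.000999000999000999
```

Reading: across the six simulated observers the fitted PSE drops from
178 ms (baseline) to 98 ms with sounds — the freezing effect (more group
motion at every interval). 7292 microsaccades were detected with an
amplitude/peak-velocity correlation of 0.91, and the frame1-locked
microsaccade rate shows one significant negative cluster from 726 to
1000 ms: the sound condition suppresses microsaccades longer during the
late (response) phase, the oculomotor signature of the effect.

The same run from a shell, writing CSV/JSON artifacts per stage:

```
ternuseye run-all --config src/ternuseye/configs/default.yaml --out out/
```

Subcommands `simulate`, `detect`, `rates`, `pupil`, `psychometric` and
`stats` expose the individual stages; all accept `--config` (YAML,
times in ms, rates in Hz) and `--seed`.

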