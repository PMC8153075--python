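# Default pipeline configuration: full Experiment-1 analysis on synthetic
# data (6 virtual participants, 336 trials each). All times in ms, rates
# in Hz.
experiments: [E1]
n_subjects: 6
seed: 0
n_iterations: 1000
alpha: 0.05
window_ms: [-500, 1000]
stats_window_ms: [0, 1000]
baseline_window_ms: [-100, 0]
locks: [frame1, frame2]
blink_pad_ms: 50
detection:
  lambda_threshold: 8.0
  min_duration_ms: 3.0
  max_duration_ms: 110.0
  min_interval_ms: 20.0
kernel:
  alpha_per_ms: 0.05
  support_ms: 200.0
  step_ms: 2.0
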