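topology: shortcuts
n_states: 200
rate: 1.0
backward_rate: 0.0
random_count: 0
random_rate_range:
- 0.01
- 0.05
random_span_range:
- 1
- 3
shortcuts:
- source: 140
  target: 40
  probability: 0.3
- source: 60
  target: 160
  probability: 0.3
ps2_n_per_cycle: 100
ps2_clearance_probability: 0.5
initial_conditions:
- random
- gaussian
- uniform
sigma: null
ic_center: 0
regime: clockwork
n_periods: 40.0
detect_periods: 8.0
desync_detect_periods: 3.0
dt: null
n_cells: null
noise_sd: 0.0
sampling_interval: null
seed: 0
name: fig6_two_shortcuts
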