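acquisition:
  sampling_frequency: 20
protocol:
  type: ascending
  loading_rate: 20
  safety_limit: 150
  n_repetitions: 3
operator:
  tracking_time_constant: 0.0
  noise_sd: 0.0
  seed: 5
subject:
  detection_threshold: 40
  pain_threshold: 80
  tolerance_threshold: 120
  reaction_time: 0.0
  seed: 6
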