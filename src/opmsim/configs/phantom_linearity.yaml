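# 17-Hz phantom linearity protocol: 8 current amplitudes x 8 repeats,
# zero background, open- vs closed-loop comparison.
kind: phantom_linearity
seed: 1
helmet:
  n_sensors: 64
  head_radius: 0.09
  standoff: 0.015
  seed: 0
sensor_model:
  sample_rate: 375.0
  noise_density: 15.0e-15
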