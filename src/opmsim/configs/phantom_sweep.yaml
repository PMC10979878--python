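# Background-field sweep: 1 mA bursts, 5 per level, 81 levels 0-8 nT,
# uniform vertical background; open- vs closed-loop comparison.
kind: phantom_sweep
seed: 1
top_k: 10
helmet:
  n_sensors: 64
  head_radius: 0.09
  standoff: 0.015
  seed: 0
sensor_model:
  sample_rate: 375.0
  noise_density: 15.0e-15
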