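# Visuo-motor paradigm: 60 circles / 120 faces / 25 catch trials (~396 s),
# gamma imaging of circles trials on a 4-mm grid.
kind: visuomotor
seed: 1
band: [52.0, 65.0]
helmet:
  n_sensors: 64
  head_radius: 0.09
  standoff: 0.015
  seed: 0
sensor_model:
  sample_rate: 375.0
  noise_density: 15.0e-15
grid:
  spacing: 0.004
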