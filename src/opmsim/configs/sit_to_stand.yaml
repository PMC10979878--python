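# Sitting-to-standing session: 8-s trials, ~2 nT movement transients,
# closed-loop sensors, beta pseudo-T image and TFS.
kind: sit_to_stand
seed: 1
helmet:
  n_sensors: 64
  head_radius: 0.09
  standoff: 0.015
  seed: 0
sensor_model:
  sample_rate: 1500.0
  noise_density: 15.0e-15
sit_to_stand:
  n_trials: 20
  field_excursion: 2.0e-9
grid:
  spacing: 0.004
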