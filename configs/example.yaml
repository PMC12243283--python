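# Desk-scale demonstration configuration for `idhgan all --config ...`
seed: 1
cohort:
  n_patients: 56
  sessions_per_patient: 20
  measurements_per_session: 18
  idh_target_prevalence: 0.1485
  missing_rate: 0.02
preprocess:
  date_mode: days_elapsed
  scaler_c: 0.5
  train_fraction: 0.75
gan:
  epochs: 30
  batch_size: 512
grid:
  n_estimators: [80, 90, 100, 110, 120, 130]
  max_depth: [8, 10, 12, 14, 16]
output_dir: runs/example
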