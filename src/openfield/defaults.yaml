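# Shipped default calibration. Saline targets: ~70% time immobile over the
# 10-60 min window, rising above 80% in the final 30 min, with corner-zone
# occupancy plurality. Drug defaults place the significant doses above ed50
# and put effect onset near 10 min with washout by 60-75 min.
arena:
  side_length: 50.0
  grid_cell: 10.0
  wall_height: 35.0
recording:
  dt: 0.03333333333333333   # 30 frames/s
  duration_s: 5400.0
behavior:
  bout_rate0: 15.0
  bout_mean_dur: 3.0
  speed_scale: 8.0
  speed_sigma: 0.5
  habituation_tau: 40.0
  round_factor: 0.85
  thigmotaxis_strength: 1.2
  heading_persistence: 4.0
  freeze_frac: 0.3
  posture_noise: 0.15
  body_length: 4.5
pharmacodynamics:
  SCH23390:
    emax: 0.92
    ed50: 0.02
    hill: 1.5
    ka: 0.2
    ke: 0.05
  haloperidol:
    emax: 0.92
    ed50: 0.2
    hill: 1.5
    ka: 0.2
    ke: 0.05
doses:
  SCH23390: [0.005, 0.01, 0.02, 0.05, 0.5]
  haloperidol: [0.05, 0.1, 0.2, 0.5, 1.0]
metrics:
  v_thresh: 1.0
  smooth_win: 0.5
  min_dur: 2.0
  gap_merge: 0.2
  filter_cap: 80.0
  min_body_length: 1.0
toi:
  start_min: 10.0
  end_min: 60.0
stats:
  alpha: 0.05
  sidak_family: per_row
design:
  n_animals: 48
  n_rounds: 4
  day_spacing: 7
seed: 1
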