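# Demo study: 4+4 simulated subjects, 5 tracks x 20 s, all three bands.
# Completes on one CPU in a few minutes.
out_dir: results/demo
seed: 7
bands: [full, delta, theta]
lambda_grid: [1.0, 100.0, 10000.0, 1000000.0]
n_perm: 200
compute_chance: false
theta_gain_patient: 2.0
sim:
  n_subjects_per_group: 4
  n_tracks: 5
  track_duration_s: 20.0
  n_channels: 32
  snr_db: -11.0
  n_bands: 16
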