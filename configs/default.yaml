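# Default end-to-end pipeline configuration.
#
# Mirrors the acquisition conditions of the analyses: a 120 x 120 px analysis
# crop at 78-nm pixels (9360 x 9360 nm), 15,000 localizations per channel,
# DoC with R_max = 500 nm / dR = 50 nm, trajectories at 4 ms/frame, TALL with
# a 50-nm detection circle and a 32-ms trapped-period threshold. One global
# seed deterministically derives every per-stage seed.
seed: 0
output_dir: results/pipeline
stages:
  simulate: true
  cluster: true
  doc: true
  track: true
  tall: true
roi:
  x_min: 0.0
  y_min: 0.0
  x_max: 9360.0
  y_max: 9360.0
scene_a:
  n_clusters: 20
  cluster_radius_sd: 45.0
  locs_per_cluster: 50
  background_locs: 5000
  localization_precision_sd: 22.0
  mean_blink_repeats: 1.5
scene_b:
  n_clusters: 20
  cluster_radius_sd: 45.0
  locs_per_cluster: 50
  background_locs: 5000
  localization_precision_sd: 26.3
  mean_blink_repeats: 1.5
coloc_fraction: 0.8
subsample_n: 15000
doc:
  r_max: 500.0
  dr: 50.0
trajectory:
  model: brownian
  D: 1.0
  frame_interval: 0.004
  n_frames: 50
  localization_precision_sd: 22.2
n_trajectories: 200
windows:
- 12ms@4ms
- 24ms@4ms
tall:
  detection_radius: 50.0
  threshold_trapped_period: 0.032
cluster:
  n_simulations: 20
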