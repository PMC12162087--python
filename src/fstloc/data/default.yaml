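# Default study conditions for the synthetic FST-localization pipeline.
# All durations in seconds, geometry in degrees of visual angle, gains and
# noise in percent-signal-change units.

seed: 0
noise_sd: 0.5
drift_slope: 0.5

hemisphere:
  shape: [64, 64]
  atlas_jitter: 2
  background_t1: [1.331, 0.01]
  # regions: omitted -> package defaults (hMT/MST 296 vertices, pFST 95,
  # V1-like 160 on the 64 x 64 sheet)

schedules:
  motion2d: {block_s: 15, reps_per_direction: 3, n_runs: 2}
  motion3d: {block_s: 10, reps: 15, n_runs: 1}
  opponent: {block_s: 15, n_blocks: 21, n_runs: 1}

aperture:
  radius: 12.2
  grid_size: 101
  n_steps: 8
  step_trs: 3
  tr: 1.0

# 12 retinotopy scans in total: half bar, half wedge/ring
prf_runs:
  n_bar: 6
  n_wedge_ring: 6

fit:
  pos_step: 1.0
  sigma_min: 0.25
  sigma_max: 24.0
  n_sigma: 20
  refine_tol: 1.0e-4

roi:
  q_start: 95
  q_min: 90
  q_step: 1
  adjacency_dist: 3

biassim:
  sizes: [1, 5, 10, 15, 20]
  eccs: [0, 3, 6, 9, 12]
  noise_levels: [0.25, 0.5, 2.0]
  n_voxels: 50
  n_boot: 100
  signal_peak: 1.0

cohort:
  n_subjects: 9
  vertex_sd: 0.3
  r1_vertex_sd: 0.02
  hemisphere_sd: 0.1
  r1_hemisphere_sd: 0.01
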