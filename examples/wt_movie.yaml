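# Simulate a wild-type two-lineage movie and run the full analysis chain.
simulation:
  duration_hours: 6.0
  frame_interval_min: 15.0
  condition: WT
  n_lineages: 2
  volume_shape_zyx: [24, 200, 200]
segmentation:
  median_radius_px: 1
  contour_iterations: 5
tracking:
  radius_px: 12.0
  max_gap_frames: 5
analysis:
  persistence_level_theta: 0.5
  persistence_min_duration_h: 4.0
output_dir: notchtrack_out
seed: 4
log_level: INFO
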