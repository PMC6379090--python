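{
 "hash": "2191489c17cb83da",
 "seed": 0,
 "config": {
  "simulation": null,
  "segmentation": {
   "median_radius_px": 1,
   "threshold_method": "otsu",
   "fixed_threshold": null,
   "contour_iterations": 5,
   "contour_smoothing": 0,
   "hmax_depth": 2.0,
   "min_volume_voxels": 90,
   "z_scale": 1.0,
   "max_foreground_fraction": 0.25
  },
  "tracking": {
   "radius_px": 12.0,
   "max_gap_frames": 5,
   "z_scale": 1.0,
   "division_size_ratio_max": 0.95
  },
  "analysis": {
   "persistence_level_theta": 0.5,
   "persistence_min_duration_h": 4.0,
   "reactivation_on_theta": 0.3,
   "reactivation_off_theta": 0.15,
   "reactivation_min_quiet_h": 2.0,
   "n_phase_bins": 20,
   "nb_diameter_px": 14.0,
   "gmc_diameter_px": 9.0,
   "similarity_ratio": 0.8
  },
  "movie_path": null,
  "output_dir": "notchtrack_out",
  "seed": 0,
  "log_level": "INFO"
 }
}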