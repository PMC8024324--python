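{
  "n_subjects": 6,
  "n_regions": 6,
  "n_categories": 8,
  "n_runs": 16,
  "n_voxels_per_region": 120,
  "n_model_layers": 11,
  "subject_loading_sd": 0.8,
  "run_noise_sd": 2.5,
  "selective_voxel_fraction": 0.1,
  "selective_offset": 5.0,
  "seed": 1
}
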