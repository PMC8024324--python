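{
  "simulation": {
    "n_subjects": 6,
    "n_regions": 6,
    "n_categories": 8,
    "n_runs": 16,
    "n_voxels_per_region": 120,
    "n_model_layers": 11,
    "subject_loading_sd": 0.8,
    "run_noise_sd": 2.5,
    "seed": 1
  },
  "top_k": 75,
  "metric": "euclidean_z",
  "comparison": "spearman",
  "q": 0.05,
  "output_dir": "scratch/report"
}
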