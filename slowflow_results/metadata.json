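{
 "config_hash": "852f68bb6c79f9d4",
 "seed": 5,
 "config": {
  "sampling_interval": 2.0,
  "n_time": 120,
  "n_realizations": 8,
  "seed": 5,
  "omega0": 6.0,
  "n_voices": 40,
  "fmin": 0.005,
  "fact_tol": 1e-07,
  "fact_max_iter": 100,
  "n_fact": 65,
  "window_len": 19,
  "n_windows": 3,
  "bands": {
   "slow-4": [
    0.027,
    0.073
   ],
   "slow-2": [
    0.198,
    0.25
   ]
  },
  "input_path": null,
  "input_format": "tsv",
  "mask_path": null,
  "spec_path": null,
  "fiber_path": null,
  "output_dir": "slowflow_results"
 },
 "causality_meta": {
  "n_iter": 9,
  "max_residual": 7.833175144368716e-10,
  "n_failed_slices": 0,
  "n_floored": 0,
  "n_clipped": 0,
  "tol": 1e-07,
  "max_iter": 100,
  "n_fact": 65
 },
 "n_realizations": 8
}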