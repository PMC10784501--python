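{
  "command": "corrupt",
  "params": {
    "gt_path": "examples/fixture_gt.json",
    "config": {
      "miss_rate": 0.05,
      "fp_rate": 0.0,
      "jitter_sd": 0.5,
      "mask_erode_dilate": 0.0,
      "score_mean": 0.9,
      "score_sd": 0.05,
      "seed": 43
    },
    "target_fps": null
  }
}
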