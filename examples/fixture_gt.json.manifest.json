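{
  "command": "simulate",
  "params": {
    "config": {
      "frame_w": 960,
      "frame_h": 540,
      "n_agents": 5,
      "fps": 10.0,
      "duration": 2.0,
      "body_a": 33.0,
      "body_b": 12.0,
      "speed_mean": 1.6,
      "speed_sd": 0.6,
      "speed_floor": 0.4,
      "heading_sd": 0.06,
      "inactive_fraction": 0.5,
      "inactive_jitter_sd": 0.05,
      "visibility_min": 0.8,
      "well_separated": true,
      "n_vertices": 16,
      "seed": 42
    }
  }
}
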