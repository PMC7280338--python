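{
  "sg": {
    "window_samples": null,
    "poly_order": 2
  },
  "quality": {
    "window_ms": 300
  },
  "classifiers": [
    {
      "id": "slow_fast",
      "entry_point": "slow_fast",
      "parameters": [
        {"name": "velocity_threshold_dps", "value": 100.0, "min": 10.0, "max": 1000.0, "user_settable": true},
        {"name": "min_fast_ms", "value": 10.0, "min": 0.0, "max": 500.0, "user_settable": true},
        {"name": "min_slow_ms", "value": 40.0, "min": 0.0, "max": 2000.0, "user_settable": true}
      ]
    }
  ],
  "export_streams": ["gaze", "imu", "quality", "coding"]
}
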