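{
  "version": "1",
  "instrument": "PMEWS admission algorithm",
  "gap_rule": "nearest_higher_score",
  "numeric_parameters": [
    {
      "name": "respiratory_rate",
      "units": "breaths/min",
      "precision": 0,
      "plausible_range": [0, 120],
      "bands": [
        {"lo": null, "hi": 8, "score": 3},
        {"lo": 9, "hi": 18, "score": 0},
        {"lo": 19, "hi": 25, "score": 1},
        {"lo": 26, "hi": 29, "score": 2},
        {"lo": 30, "hi": null, "score": 3}
      ]
    },
    {
      "name": "spo2",
      "units": "%",
      "precision": 0,
      "plausible_range": [0, 100],
      "bands": [
        {"lo": null, "hi": 88, "score": 3},
        {"lo": 90, "hi": 93, "score": 2},
        {"lo": 94, "hi": 96, "score": 1},
        {"lo": 97, "hi": null, "score": 0}
      ]
    },
    {
      "name": "heart_rate",
      "units": "beats/min",
      "precision": 0,
      "plausible_range": [0, 300],
      "bands": [
        {"lo": null, "hi": 40, "score": 3},
        {"lo": 41, "hi": 50, "score": 2},
        {"lo": 51, "hi": 100, "score": 0},
        {"lo": 101, "hi": 110, "score": 1},
        {"lo": 111, "hi": 129, "score": 2},
        {"lo": 130, "hi": null, "score": 3}
      ]
    },
    {
      "name": "systolic_bp",
      "units": "mmHg",
      "precision": 0,
      "plausible_range": [0, 350],
      "bands": [
        {"lo": null, "hi": 70, "score": 3},
        {"lo": 71, "hi": 90, "score": 2},
        {"lo": 91, "hi": 100, "score": 1},
        {"lo": 101, "hi": null, "score": 0}
      ]
    },
    {
      "name": "temperature",
      "units": "degC",
      "precision": 1,
      "plausible_range": [25.0, 45.0],
      "bands": [
        {"lo": null, "hi": 35.0, "score": 2},
        {"lo": 35.1, "hi": 36.0, "score": 1},
        {"lo": 36.1, "hi": 37.9, "score": 0},
        {"lo": 38.0, "hi": 38.9, "score": 1},
        {"lo": 39.0, "hi": null, "score": 2}
      ]
    }
  ],
  "consciousness_levels": {
    "alert": 0,
    "confused_agitated": 1,
    "voice": 2,
    "pain_unresponsive": 3
  }
}
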