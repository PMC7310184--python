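{
  "description": "Default MEWS banding (widely used aggregate-weighted scheme; institutional EMR implementations vary and every edge here is configurable). Bands are half-open [lo, hi) on the measured scale; temperature in degrees Celsius.",
  "components": {
    "heart_rate": [
      {"lo": 10, "hi": 41, "points": 2},
      {"lo": 41, "hi": 51, "points": 1},
      {"lo": 51, "hi": 101, "points": 0},
      {"lo": 101, "hi": 111, "points": 1},
      {"lo": 111, "hi": 130, "points": 2},
      {"lo": 130, "hi": 300, "points": 3}
    ],
    "respiratory_rate": [
      {"lo": 0, "hi": 9, "points": 2},
      {"lo": 9, "hi": 15, "points": 0},
      {"lo": 15, "hi": 21, "points": 1},
      {"lo": 21, "hi": 30, "points": 2},
      {"lo": 30, "hi": 80, "points": 3}
    ],
    "systolic_bp": [
      {"lo": 20, "hi": 71, "points": 3},
      {"lo": 71, "hi": 81, "points": 2},
      {"lo": 81, "hi": 101, "points": 1},
      {"lo": 101, "hi": 200, "points": 0},
      {"lo": 200, "hi": 300, "points": 2}
    ],
    "temperature": [
      {"lo": 25.0, "hi": 35.0, "points": 2},
      {"lo": 35.0, "hi": 38.5, "points": 0},
      {"lo": 38.5, "hi": 45.0, "points": 2}
    ]
  },
  "avpu": {
    "alert": 0,
    "voice": 1,
    "pain": 2,
    "unresponsive": 3
  }
}
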