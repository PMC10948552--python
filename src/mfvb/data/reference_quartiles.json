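{
  "version": "1.0",
  "description": "Reference 25th/75th percentile bands for the eight MFVB vocal features, from a large clinical voice biobank, with each feature's direction of correlation with depression ('+' means larger values accompany more severe symptoms).",
  "features": {
    "jitter_pct": {"q25": 4.9, "q75": 7.8, "direction": "+", "units": "%"},
    "shimmer_pct": {"q25": 2.5, "q75": 6.6, "direction": "+", "units": "%"},
    "pitch_variability_oct": {"q25": 0.15, "q75": 0.28, "direction": "-", "units": "octaves"},
    "energy_variability_db": {"q25": 6.9, "q75": 9.5, "direction": "-", "units": "dB"},
    "vowel_space_mhz2": {"q25": 0.33, "q75": 0.43, "direction": "-", "units": "MHz^2"},
    "phonation_duration_ms": {"q25": 201.0, "q75": 294.0, "direction": "-", "units": "msec"},
    "speech_rate_wpm": {"q25": 75.0, "q75": 125.0, "direction": "-", "units": "words/min"},
    "pause_duration_s": {"q25": 0.31, "q75": 0.61, "direction": "+", "units": "sec"}
  }
}
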