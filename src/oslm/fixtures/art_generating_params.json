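{
  "description": "Default generating parameters for ART-like simulation studies: component initial difficulties and practice effects at realistic magnitudes, with person-varying practice effects for A/S and distortion.",
  "version": 1,
  "components": [
    {"name": "CR", "kind": "rule"},
    {"name": "PP", "kind": "rule"},
    {"name": "A/S", "kind": "rule"},
    {"name": "D3", "kind": "rule"},
    {"name": "D2", "kind": "rule"},
    {"name": "overlay", "kind": "figural"},
    {"name": "distortion", "kind": "figural"},
    {"name": "fusion", "kind": "figural"}
  ],
  "alpha": {
    "CR": -1.585,
    "PP": 1.017,
    "A/S": -0.538,
    "D3": 0.045,
    "D2": 0.213,
    "overlay": -0.503,
    "distortion": -0.004,
    "fusion": -0.906
  },
  "practice": {
    "CR": {"mode": "fixed", "value": -0.090},
    "PP": {"mode": "fixed", "value": 0.095},
    "A/S": {"mode": "random", "mu": -0.022, "sigma": 0.0547722557505},
    "D3": {"mode": "fixed", "value": -0.004},
    "D2": {"mode": "fixed", "value": -0.060},
    "overlay": {"mode": "fixed", "value": -0.066},
    "distortion": {"mode": "random", "mu": -0.017, "sigma": 0.2049390153191},
    "fusion": {"mode": "fixed", "value": -0.125}
  },
  "Omega": [[1.0, 0.0], [0.0, 1.0]]
}
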