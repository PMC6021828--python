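{
  "format_version": 1,
  "variant_id": "linear_quadratic",
  "a": [[80.0, 0.32], [61.0, 1.47]],
  "b": [[0.15, 0.41], [-0.13, 0.01]],
  "d": [-0.16, -0.22],
  "r": [0.6, 0.44],
  "meta": {
    "description": "Reference least-squares calibration of an SB-30 SnO2 sensor in dual-temperature mode (heater 0.5 V / 0.9 V, i.e. 131 C / 462 C) on 39 acetone-ethanol mixtures in dry air (acetone 0-20 ppm, ethanol 0-40 ppm).",
    "gases": ["acetone", "ethanol"],
    "temperatures_heater_V": [0.5, 0.9]
  }
}
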