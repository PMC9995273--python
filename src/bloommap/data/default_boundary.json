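{
  "left_coeffs": [4.8093, -3.0958, 0.8357],
  "right_coeffs": [4.9040, -3.5759, 0.9862],
  "split": 0.3333333333333333,
  "percentile": 0.01,
  "provenance": "trained CIE-fluorescence boundary (shipped default)"
}
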