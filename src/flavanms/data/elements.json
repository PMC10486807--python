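{
  "C": {"nominal": 12, "monoisotopic": 12.0},
  "H": {"nominal": 1, "monoisotopic": 1.00782503207},
  "O": {"nominal": 16, "monoisotopic": 15.99491461957}
}
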