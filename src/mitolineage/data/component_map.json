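{
  "western_eurasian": ["N1", "N2", "N3", "X", "R0", "R2'JT", "U"],
  "eastern_eurasian": ["A4", "B4", "C4", "C5", "D4", "F1b1", "G2a3", "C"],
  "south_asian": ["M2", "M3", "M4", "M5", "M18", "M42", "R5", "R8", "R30", "U2c", "U2d"],
  "african": ["L2a", "L3d", "L3e", "L3f", "L5c"]
}
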