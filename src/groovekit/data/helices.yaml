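# Default transmembrane-helix residue ranges (fungal scramblase numbering).
# Approximate spans chosen to lie inside the segments modeled in the
# deposited structures; override per run via the config file.
tm_helices:
  TM1: [197, 226]
  TM2: [235, 262]
  TM3: [292, 319]
  TM4: [326, 353]
  TM5: [363, 390]
  TM6: [430, 465]
  TM7: [495, 518]
  TM8: [523, 550]
  TM9: [556, 582]
  TM10: [600, 630]
groove_helices: [TM3, TM4, TM5, TM6]
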