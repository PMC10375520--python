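{
  "H": 0.31,
  "C": 0.76,
  "N": 0.71,
  "O": 0.66,
  "S": 1.05,
  "F": 0.57,
  "P": 1.07,
  "Cl": 1.02,
  "Na": 1.66,
  "Ca": 1.76,
  "Mg": 1.41,
  "K": 2.03
}
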