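{
  "version": "additive-atom-types-v1",
  "comment": "Per-heavy-atom additive contributions to an octanol/water logP estimate. Types are keyed on element, aromaticity and heteroatom neighbourhood; see docs/methods.md.",
  "contributions": {
    "C.aliphatic": 0.5,
    "C.aliphatic.het": 0.08,
    "C.aromatic": 0.31,
    "C.aromatic.het": 0.14,
    "N.aliphatic": -0.9,
    "N.aromatic": -0.5,
    "O.hydroxyl": -0.4,
    "O.ether": -0.1,
    "O.carbonyl": -0.2,
    "O.aromatic": -0.08,
    "S.any": 0.25,
    "P.any": -0.5,
    "F": 0.2,
    "Cl": 0.7,
    "Br": 0.9,
    "I": 1.1
  },
  "element_defaults": {
    "B": 0.0,
    "C": 0.3,
    "N": -0.7,
    "O": -0.2,
    "S": 0.25,
    "P": -0.5,
    "H": 0.0
  }
}
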