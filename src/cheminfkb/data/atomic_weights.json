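{
  "version": "2021-averages-3dp",
  "weights": {
    "H": 1.008,
    "B": 10.811,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.060,
    "Cl": 35.453,
    "Br": 79.904,
    "I": 126.904
  }
}
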