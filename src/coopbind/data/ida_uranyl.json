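{
  "comment": "Default iminodiacetate (IDA) model for uranyl competition at 25 C, I = 0.1 M. These are user-replaceable literature values (acid-dissociation exponents and cumulative formation constants referenced to free UO2(2+) and fully deprotonated IDA); replace them with your preferred critically evaluated set before quantitative work.",
  "chelator": {
    "pKa": [9.34, 2.61],
    "species": [
      {"m": 1, "l": 1, "log10_beta": 8.93},
      {"m": 1, "l": 2, "log10_beta": 16.2},
      {"m": 2, "l": 2, "log10_beta": 18.5}
    ]
  },
  "conditions": {"pH": 6.0, "T": 298.0, "ionic_strength": 0.1}
}
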