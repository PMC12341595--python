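{
  "regions": [
    {"name": "IH1", "start": 3, "end": 20},
    {"name": "IH2", "start": 667, "end": 673},
    {"name": "NBD1", "start": 903, "end": 1147},
    {"name": "R1", "start": 1182, "end": 1251},
    {"name": "IH3", "start": 1327, "end": 1344},
    {"name": "IH4", "start": 1684, "end": 1690},
    {"name": "NBD2", "start": 1907, "end": 2143},
    {"name": "R2", "start": 2155, "end": 2220}
  ],
  "motifs": [
    {"name": "Walker_A", "domain": "NBD1", "start": 926, "end": 942},
    {"name": "signature", "domain": "NBD1", "start": 1033, "end": 1040},
    {"name": "Walker_B", "domain": "NBD1", "start": 1056, "end": 1065},
    {"name": "Walker_A", "domain": "NBD2", "start": 1939, "end": 1955},
    {"name": "signature", "domain": "NBD2", "start": 2045, "end": 2052},
    {"name": "Walker_B", "domain": "NBD2", "start": 2068, "end": 2077}
  ],
  "features": [
    {"name": "crossover", "start": 1229, "end": 1254},
    {"name": "crossback", "start": 2198, "end": 2223}
  ]
}
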