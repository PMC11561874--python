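{
  "interferents": [
    {"name": "CO2-bend", "correct_region": [600, 914], "gamma_region": null},
    {"name": "H2O-bend", "correct_region": [1205, 2072], "gamma_region": null},
    {"name": "CO2-asym-stretch", "correct_region": [2208, 2442], "gamma_region": null},
    {"name": "H2O-stretch", "correct_region": [3231, 4000], "gamma_region": null},
    {"name": "CO2-comb-overtone-stretch", "correct_region": [3602, 3627], "gamma_region": null},
    {"name": "CO2-comb-bend-stretch", "correct_region": [3701, 3731], "gamma_region": null}
  ]
}
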