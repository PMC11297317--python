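{
  "description": "External cell-line validation of the published breast IHC localization model: proteins with known MCF7 locations whose predicted localization was checked for consistency.",
  "n_proteins": 25,
  "n_consistent": 19
}
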