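{
  "news2_bands.csv": "1.0",
  "fio2_mapping.csv": "1.0",
  "normal_bands.csv": "1.0",
  "feature_manifest": "1.0"
}
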