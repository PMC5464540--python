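{
 "scales": {
  "prok_abundance": 100000.0,
  "viral_abundance": 1000000.0,
  "vp": 10000.0
 }
}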