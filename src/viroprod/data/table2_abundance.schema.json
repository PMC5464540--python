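{
 "scales": {
  "prok_avg": 100000.0,
  "prok_sd": 100000.0,
  "virus_avg": 10000000.0,
  "virus_sd": 10000000.0
 }
}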