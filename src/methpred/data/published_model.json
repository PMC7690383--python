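{
  "probe_ids": ["cg01072658", "cg03085846", "cg13770628"],
  "weights": [-19.3, -11.2, -24.6],
  "threshold": -35.9,
  "scale": "array",
  "orientation": "pCR_high"
}
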