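{
  "name": "CasRx",
  "target_type": "RNA",
  "pam_side": "none",
  "spacer_length": 23,
  "cut_offset": null
}
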