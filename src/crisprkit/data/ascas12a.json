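{
  "name": "AsCas12a",
  "target_type": "DNA",
  "pam_side": "5prime",
  "pam_patterns": [["TTTV", 1.0]],
  "spacer_length": 23,
  "cut_offset": 21
}
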