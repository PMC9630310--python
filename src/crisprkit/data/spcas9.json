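{
  "name": "SpCas9",
  "target_type": "DNA",
  "pam_side": "3prime",
  "pam_patterns": [["NGG", 1.0], ["NAG", 0.26]],
  "spacer_length": 20,
  "cut_offset": -4
}
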