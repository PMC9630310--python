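{
  "name": "BE4max",
  "_comment": "Synthetic placeholder editing weights. The window positions cover protospacer positions 3-10 (relative coordinates -18..-11 for a 20-nt spacer with a 3' PAM); the C->T probabilities are a smooth peak at protospacer position 6 intended for testing and must be replaced by experimentally derived weights before use in a real design. Editing acts on the protospacer-containing strand.",
  "base": {
    "name": "BE4max",
    "target_type": "DNA",
    "pam_side": "3prime",
    "pam_patterns": [["NGG", 1.0]],
    "spacer_length": 20,
    "cut_offset": -4
  },
  "editing_strand": "protospacer",
  "window_positions": [-18, -17, -16, -15, -14, -13, -12, -11],
  "editing_weights": [
    {"position": -18, "from": "C", "to": "T", "probability": 0.10},
    {"position": -17, "from": "C", "to": "T", "probability": 0.30},
    {"position": -16, "from": "C", "to": "T", "probability": 0.55},
    {"position": -15, "from": "C", "to": "T", "probability": 0.70},
    {"position": -14, "from": "C", "to": "T", "probability": 0.55},
    {"position": -13, "from": "C", "to": "T", "probability": 0.30},
    {"position": -12, "from": "C", "to": "T", "probability": 0.10},
    {"position": -11, "from": "C", "to": "T", "probability": 0.05}
  ]
}
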