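{
  "version": "1.0",
  "description": "BI-RADS mass-descriptor vocabulary and malignancy-probability quantification codes (malignant 1, uncertain 0.5, benign 0).",
  "fields": ["shape", "margin_sharpness", "microlobulated", "spiculated", "density"],
  "codes": {
    "shape": {"oval": 0.0, "round": 0.0, "irregular": 1.0},
    "margin_sharpness": {"circumscribed": 0.0, "obscured": 0.5, "indistinct": 1.0},
    "microlobulated": {"no": 0.0, "yes": 1.0},
    "spiculated": {"no": 0.0, "yes": 1.0},
    "density": {"low": 0.0, "fat-containing": 0.0, "equal": 0.5, "high": 1.0}
  }
}
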