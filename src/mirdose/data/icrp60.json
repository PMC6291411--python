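{
  "scheme_id": "ICRP60",
  "weights": {
    "gonads": 0.20,
    "red_marrow": 0.12,
    "colon": 0.12,
    "lungs": 0.12,
    "stomach_wall": 0.12,
    "urinary_bladder_wall": 0.05,
    "breast": 0.05,
    "liver": 0.05,
    "esophagus": 0.05,
    "thyroid": 0.05,
    "skin": 0.01,
    "bone_surfaces": 0.01
  },
  "remainder": {
    "weight": 0.05,
    "rule": "most_exposed_split",
    "tissues": [
      "adrenals",
      "brain",
      "right_colon",
      "small_intestine",
      "kidneys",
      "muscle",
      "pancreas",
      "spleen",
      "thymus",
      "uterus"
    ]
  },
  "composites": {
    "colon": ["left_colon", "rectum"]
  }
}
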