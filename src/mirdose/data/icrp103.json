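{
  "scheme_id": "ICRP103",
  "weights": {
    "red_marrow": 0.12,
    "colon": 0.12,
    "lungs": 0.12,
    "stomach_wall": 0.12,
    "breast": 0.12,
    "gonads": 0.08,
    "urinary_bladder_wall": 0.04,
    "esophagus": 0.04,
    "liver": 0.04,
    "thyroid": 0.04,
    "bone_surfaces": 0.01,
    "brain": 0.01,
    "salivary_glands": 0.01,
    "skin": 0.01
  },
  "remainder": {
    "weight": 0.12,
    "rule": "mean",
    "tissues": [
      "adrenals",
      "extrathoracic_region",
      "gallbladder_wall",
      "heart_wall",
      "kidneys",
      "lymphatic_nodes",
      "muscle",
      "oral_mucosa",
      "pancreas",
      "prostate",
      "small_intestine",
      "spleen",
      "thymus",
      "uterus"
    ]
  },
  "composites": {
    "colon": ["right_colon", "left_colon", "rectum"]
  }
}
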