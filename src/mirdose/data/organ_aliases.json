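{
  "whole_body": "total_body",
  "body": "total_body",
  "wb": "total_body",
  "ub_wall": "urinary_bladder_wall",
  "bladder_wall": "urinary_bladder_wall",
  "urinary_bladder": "urinary_bladder_contents",
  "ub_contents": "urinary_bladder_contents",
  "ub_cont": "urinary_bladder_contents",
  "bladder_contents": "urinary_bladder_contents",
  "bladder": "urinary_bladder_contents",
  "gb_wall": "gallbladder_wall",
  "gallbladder": "gallbladder_contents",
  "gb_contents": "gallbladder_contents",
  "gb_cont": "gallbladder_contents",
  "uli": "right_colon",
  "upper_large_intestine": "right_colon",
  "lli": "left_colon",
  "lower_large_intestine": "left_colon",
  "si": "small_intestine",
  "small_intestine_wall": "small_intestine",
  "bone_marrow": "red_marrow",
  "marrow": "red_marrow",
  "rectosigmoid": "rectum",
  "heart": "heart_wall",
  "stomach": "stomach_wall",
  "testis": "testes",
  "ovary": "ovaries",
  "osteogenic_cells": "bone_surfaces",
  "bone_surface": "bone_surfaces",
  "kidney": "kidneys",
  "lung": "lungs",
  "adrenal_glands": "adrenals",
  "salivary_gland": "salivary_glands"
}
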