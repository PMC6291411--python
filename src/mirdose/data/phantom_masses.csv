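organ,mass_g,phantom_id
adrenals,14,male_2.0
brain,1450,male_2.0
esophagus,40,male_2.0
gallbladder_wall,10,male_2.0
right_colon,150,male_2.0
left_colon,150,male_2.0
rectum,70,male_2.0
small_intestine,650,male_2.0
stomach_wall,150,male_2.0
heart_wall,330,male_2.0
kidneys,310,male_2.0
liver,1800,male_2.0
lungs,1200,male_2.0
pancreas,140,male_2.0
prostate,17,male_2.0
salivary_glands,85,male_2.0
red_marrow,1170,male_2.0
bone_surfaces,4400,male_2.0
spleen,150,male_2.0
testes,35,male_2.0
thymus,25,male_2.0
thyroid,20,male_2.0
urinary_bladder_wall,50,male_2.0
breast,25,male_2.0
muscle,29000,male_2.0
skin,3300,male_2.0
lymphatic_nodes,730,male_2.0
oral_mucosa,10,male_2.0
extrathoracic_region,15,male_2.0
eyes,15,male_2.0
total_body,73000,male_2.0
adrenals,13,female_2.0
brain,1300,female_2.0
breast,500,female_2.0
esophagus,35,female_2.0
gallbladder_wall,8,female_2.0
right_colon,145,female_2.0
left_colon,145,female_2.0
rectum,70,female_2.0
small_intestine,600,female_2.0
stomach_wall,140,female_2.0
heart_wall,250,female_2.0
kidneys,275,female_2.0
liver,1400,female_2.0
lungs,950,female_2.0
ovaries,11,female_2.0
pancreas,120,female_2.0
salivary_glands,70,female_2.0
red_marrow,900,female_2.0
bone_surfaces,3600,female_2.0
spleen,130,female_2.0
thymus,20,female_2.0
thyroid,17,female_2.0
urinary_bladder_wall,40,female_2.0
uterus,80,female_2.0
muscle,17500,female_2.0
skin,2300,female_2.0
lymphatic_nodes,600,female_2.0
oral_mucosa,8,female_2.0
extrathoracic_region,12,female_2.0
eyes,15,female_2.0
total_body,60000,female_2.0
pancreas,94.3,male_1.1
red_marrow,1120,male_1.1
total_body,73700,male_1.1
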