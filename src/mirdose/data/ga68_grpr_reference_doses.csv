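organ,residence_time_h,residence_time_sd_h,dose_male_0p5h,dose_male_1h,dose_female_1h,dose_reference_1h
adrenals,2.48E-04,8.49E-05,1.48E-02,1.46E-02,1.57E-02,1.52E-02
brain,1.53E-03,1.05E-03,1.71E-03,1.71E-03,3.62E-03,2.68E-03
breast,,,,,1.06E-02,1.06E-02
esophagus,,,1.06E-02,1.06E-02,1.25E-02,1.16E-02
eyes,,,8.39E-03,8.39E-03,1.02E-02,9.32E-03
gallbladder_wall,3.60E-03,1.27E-03,2.69E-02,2.69E-02,2.19E-02,1.99E-02
left_colon,6.73E-03,3.33E-03,3.37E-02,3.38E-02,3.27E-02,3.08E-02
small_intestine,4.01E-02,1.71E-02,3.88E-02,3.90E-02,4.04E-02,3.76E-02
stomach_wall,4.79E-03,2.45E-03,1.92E-02,1.92E-02,2.00E-02,1.91E-02
right_colon,1.35E-02,6.66E-03,3.21E-02,3.22E-02,3.28E-02,3.00E-02
rectum,6.73E-03,3.33E-03,3.18E-02,3.25E-02,3.58E-02,3.17E-02
heart_wall,2.16E-02,5.45E-03,2.13E-02,2.13E-02,2.70E-02,2.42E-02
kidneys,2.14E-02,2.23E-03,3.48E-02,3.48E-02,3.31E-02,3.40E-02
liver,3.79E-02,2.93E-03,1.41E-02,1.41E-02,1.85E-02,1.63E-02
lungs,2.88E-02,5.98E-03,1.34E-02,1.34E-02,1.66E-02,1.50E-02
ovaries,,,,,1.50E-02,1.49E-02
pancreas,8.13E-02,1.95E-02,2.60E-01,2.60E-01,2.43E-01,
prostate,,,1.22E-02,1.33E-02,,1.33E-02
salivary_glands,,,9.12E-03,9.12E-03,1.07E-02,9.93E-03
red_marrow,7.10E-03,8.59E-04,9.38E-03,9.49E-03,1.17E-02,1.17E-02
bone_surfaces,,,6.83E-03,6.89E-03,7.71E-03,7.87E-03
spleen,3.16E-03,6.73E-04,1.37E-02,1.37E-02,1.55E-02,1.46E-02
testes,,,9.56E-03,9.82E-03,,9.82E-03
thymus,,,1.02E-02,1.02E-02,1.29E-02,1.15E-02
thyroid,3.20E-04,5.00E-05,9.32E-03,9.15E-03,1.05E-02,9.85E-03
urinary_bladder_wall,8.77E-02,1.69E-02,6.98E-02,1.12E-01,1.39E-01,1.25E-01
uterus,,,,,1.78E-02,1.76E-02
total_body,,,1.14E-02,1.17E-02,1.43E-02,1.30E-02
effective_dose_icrp103,,,1.76E-02,1.88E-02,2.30E-02,2.17E-02
effective_dose_icrp60,,,,2.79E-02,,3.1E-02
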