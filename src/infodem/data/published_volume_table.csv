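disease,messages,correction_factor_pct,corrected_count,users
breast cancer,39169,100,39156,19960
leukemia,9129,95.1,8682,5855
lung cancer,5745,92.6,5317,3719
lymphoma,5276,93.4,4927,2758
ovarian cancer,3063,99.9,3060,1212
pancreatic cancer,3231,100,3231,1189
prostate cancer,4487,100,4487,2311
skin cancer,7866,99.9,7859,4048
asthma,18082,92.6,16742,10185
copd,2137,77.1,1648,726
diabetes,41615,96.6,40217,16321
heart disease,14740,92.7,13669,7992
hypertension,18404,93.7,17245,12203
stroke,53858,15.1,8141,34298
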