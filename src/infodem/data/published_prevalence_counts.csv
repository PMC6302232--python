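disease,patients,state_population
breast cancer,306127,12702379
diabetes,2189890,12702379
hypertension,4614776,12702379
copd,1083627,12702379
heart disease,2461721,12702379
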