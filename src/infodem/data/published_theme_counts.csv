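disease,theme,messages,disease_total
breast cancer,Awareness,9139,39156
asthma,Awareness,1040,16742
asthma,Personal Experience,4046,16742
prostate cancer,Personal Experience,578,4487
heart disease,Risk Factor,1375,13669
lymphoma,Risk Factor,105,4927
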