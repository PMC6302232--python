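# Default 14-disease keyword lexicon (editable stand-in derived from
# consumer health vocabulary conventions; substitute your own lists for
# real studies).  Phrases are lowercase, 1-4 tokens.
breast cancer:
  - breast cancer
  - "#breastcancer"
leukemia:
  - leukemia
  - leukaemia
lung cancer:
  - lung cancer
lymphoma:
  - lymphoma
  - hodgkin's lymphoma
ovarian cancer:
  - ovarian cancer
pancreatic cancer:
  - pancreatic cancer
prostate cancer:
  - prostate cancer
skin cancer:
  - skin cancer
  - melanoma
asthma:
  - asthma
  - asthma attack
copd:
  - copd
  - emphysema
  - chronic bronchitis
diabetes:
  - diabetes
  - diabetic
heart disease:
  - heart disease
  - heart attack
  - cardiac arrest
hypertension:
  - hypertension
  - high blood pressure
stroke:
  - stroke
  - mini stroke
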