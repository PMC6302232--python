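# Small demo pipeline: 2,000 messages, 10 topics, 4 themes.
# Runs end to end in a few minutes on one CPU.
seed: 7
generator:
  n_users: 300
  n_messages: 2000
  counties:
    alder: 4000
    birch: 5000
    cedar: 3000
    dogwood: 6000
  lexicon:
    asthma: [asthma, asthma attack]
    stroke: [stroke]
    diabetes: [diabetes, diabetic]
    breast cancer: [breast cancer]
  keyword_relevance:
    asthma: 0.95
    asthma attack: 0.9
    stroke: 0.15
    diabetes: 0.92
    diabetic: 0.85
    breast cancer: 1.0
  n_themes: 4
  n_topics: 10
  vocab_size: 300
  theme_topic_conc: 0.2
  topic_word_conc: 0.08
  disease_theme_bias:
    asthma: {0: 6.0}
    stroke: {1: 4.0}
    diabetes: {2: 6.0}
    breast cancer: {3: 6.0}
  keyword_rate: 0.4
  geo_noise: {coordinates: 0.5, location_field: 0.4, unmappable: 0.1}
lda: {K: 10, n_iter: 150, burn_in: 50, beta: 0.01, min_author_frac: 0.02}
themes: {T: 4, n_iter: 400, names: [Personal Experience, Slang or Popular Culture Reference, Diet and Prevention, Awareness]}
correction: {sample_size: 30}
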