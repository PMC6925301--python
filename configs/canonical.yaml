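classifiers:
- lda
- svm_l
log_level: INFO
preprocess:
  enabled: false
protocol:
  k: 10
  repeats: 10
ranking:
  C: 1.0
  standardize: true
seed: 1
simulation:
  cov_family: compound_symmetry
  epsilon: 2.25
  n1: 150
  n2: 150
  p: 25
  rho: 0.2
  sigma: 1.0
sweep:
  fractions:
  - 0.1
  - 0.2
  - 0.3
  - 0.4
  - 0.5
  - 1.0
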