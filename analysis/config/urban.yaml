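# screening-model operating points (community test set) and
# illustrative prevalences for the hypothetical cohort
analysis:
  alpha: 0.05
  grid:
    start: 0.01
    step: 0.01
    stop: 0.99
  pairwise: 3
  positive_rule: exact_class
cohort:
  diseases:
  - AMD
  - DR
  - PM
  prevalence:
    AMD: 0.031
    DR: 0.024
    PM: 0.011
  size: 100000
models:
  Model S:
    sensitivity:
      AMD: 0.6132404181
      DR: 0.7893175074
      PM: 0.5960264901
    specificity: 0.7766816143
  Model Y:
    sensitivity:
      AMD: 0.5923344948
      DR: 0.7121661721
      PM: 0.7218543046
    specificity: 0.73632287
  RETFound-enhanced:
    sensitivity:
      AMD: 0.7595818815
      DR: 0.9525222552
      PM: 1.0
    specificity: 0.9246636771
out_dir: results/pipeline_urban
seed: 1
setting_label: urban
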