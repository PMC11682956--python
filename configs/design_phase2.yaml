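bands:
- - 10
  - 15
  - 2
- - 15
  - 25
  - 4
- - 25
  - 38
  - 7
- - 38
  - 52
  - 10
- - 52
  - null
  - 14
arm_ratios:
  placebo: 1.0
  low: 1.0
  high: 1.0
visit_days:
- 0.0
- 84.0
- 168.0
- 252.0
treatment_end: 168.0
titration_days: 14.0
titration_factor: 0.5
crossover_day: 84.0
bid_interval: 0.5
dropout_prob: 0.0
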