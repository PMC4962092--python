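# UK-style additive EQ-5D-3L time-trade-off tariff (coefficient table).
# Scoring: u = 1 - any_dysfunction_constant * I(any level > 1)
#            - sum of per-dimension level decrements
#            - extreme_level_constant * I(any level == 3)
# Worst state (3,3,3,3,3) scores -0.594; states below 0 are worse than death.
name: UK-TTO
any_dysfunction_constant: 0.081
extreme_level_constant: 0.269
decrements:
  mobility: {2: 0.069, 3: 0.314}
  self_care: {2: 0.104, 3: 0.214}
  usual_activities: {2: 0.036, 3: 0.094}
  pain_discomfort: {2: 0.123, 3: 0.386}
  anxiety_depression: {2: 0.071, 3: 0.236}
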