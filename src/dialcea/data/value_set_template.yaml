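# Template for a user-supplied EQ-5D-3L value set (e.g. a Taiwanese tariff,
# whose coefficients are not shipped here). Fill in every field; decrements
# must be >= 0 and are given for levels 2 and 3 of each dimension.
#
# Scoring model (additive):
#   u = 1 - any_dysfunction_constant * I(any level > 1)
#         - sum of per-dimension level decrements
#         - extreme_level_constant * I(any level == 3)
name: MY-TARIFF
any_dysfunction_constant: 0.0
extreme_level_constant: 0.0
decrements:
  mobility: {2: 0.0, 3: 0.0}
  self_care: {2: 0.0, 3: 0.0}
  usual_activities: {2: 0.0, 3: 0.0}
  pain_discomfort: {2: 0.0, 3: 0.0}
  anxiety_depression: {2: 0.0, 3: 0.0}
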