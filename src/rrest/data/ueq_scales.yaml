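# Standard 26-item User Experience Questionnaire: item-to-scale assignment.
#
# Responses are expected on the -3..+3 scale with +3 already oriented
# toward the positive pole of each item pair; `polarity` (one entry per
# item, +1 or -1) lets a differently coded export be described without
# code changes.

scales:
  attractiveness: [1, 12, 14, 16, 24, 25]
  perspicuity: [2, 4, 13, 21]
  efficiency: [9, 20, 22, 23]
  dependability: [8, 11, 17, 19]
  stimulation: [5, 6, 7, 18]
  novelty: [3, 10, 15, 26]

polarity: [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1,
           1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1]
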