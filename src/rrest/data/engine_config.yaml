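# Default engine configuration.
#
# Clinical constants follow the AHA PALS guideline values:
#   - rhythm check every 2 minutes;
#   - epinephrine 0.01 mg/kg (max 1 mg) of the 0.1 mg/mL (1:10,000) dilution,
#     repeated every 3-5 minutes (timer default: 180 s, the conservative
#     lower bound);
#   - defibrillation 2 J/kg, then 4 J/kg, then >=4 J/kg up to 10 J/kg,
#     never above 360 J;
#   - metronome 100-120 compressions/minute.

rhythm_check_timer: {name: rhythm_check, period_s: 120, priority_rank: 2, repeating: true}
medication_timer: {name: medication, period_s: 180, priority_rank: 1, repeating: true}
medication_timer_start: first_administration

doses:
  epinephrine:
    drug: epinephrine
    per_kg: 0.01          # mg/kg
    max_total: 1.0        # mg
    concentration: 0.1    # mg/mL (1:10,000 dilution)
    round_to: 2
    dilution_label: "1:10000"

energy:
  first_j_per_kg: 2.0
  second_j_per_kg: 4.0
  subsequent_j_per_kg: 4.0
  cap_j_per_kg: 10.0
  absolute_cap_j: 360.0

metronome_min_bpm: 100
metronome_max_bpm: 120
max_weight_kg: 100.0
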