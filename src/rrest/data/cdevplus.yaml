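# 16-item deviation checklist for a nonshockable pediatric cardiac-arrest
# scenario.  Each item states a correct critical action; a team scores 0 on
# an item when the action was performed correctly and timely, 1 otherwise,
# for a total of 0-16 (higher = more deviations from guidelines).
#
# Items marked `reconstructed: true` are standard PALS critical actions used
# to pad the instrument to 16 items; the unmarked ones correspond to the
# deviation categories the source pilot study reports (ratio, epinephrine
# dose/dilution and timing, reversible causes including hypovolemia).
# Timeliness windows are configuration values, editable per scenario.
#
# Rule kinds:
#   tap             - a performed action tap exists (buttons, optional time
#                     window from case start or CA recognition, optional
#                     payload constraints)
#   all             - every sub-rule holds
#   max_interval    - repeated event with bounded consecutive gaps
#   interval_range  - gaps between repeated actions inside [min, max]
#   resume_within   - a follow-up action within a window after every
#                     (non-organized) rhythm check

items:
  - id: cd01_timely_recognition
    description_key: item.recognition_timely
    reconstructed: true
    rule: {kind: tap, buttons: [recognize_ca], within_s: 60, from: start}

  - id: cd02_call_for_help
    description_key: item.help_called
    reconstructed: true
    rule: {kind: tap, buttons: [call_help]}

  - id: cd03_early_compressions
    description_key: item.compressions_started_early
    reconstructed: true
    rule: {kind: tap, buttons: [start_compressions], within_s: 60, from: recognition}

  - id: cd04_compression_ventilation_ratio
    description_key: item.correct_compression_ventilation_ratio
    reconstructed: false
    rule:
      kind: tap
      buttons: [set_cpr_ratio]
      payload_equals: {ratio: "15:2"}

  - id: cd05_compression_rate
    description_key: item.compression_rate_in_band
    reconstructed: true
    rule:
      kind: tap
      buttons: [start_compressions]
      payload_range: {rate_cpm: [100, 120]}

  - id: cd06_monitor_attached
    description_key: item.monitor_attached_early
    reconstructed: true
    rule: {kind: tap, buttons: [attach_monitor], within_s: 120, from: recognition}

  - id: cd07_rhythm_check_cadence
    description_key: item.rhythm_checked_every_2min
    reconstructed: true
    rule:
      kind: max_interval
      event: RHYTHM_SELECTED
      max_gap_s: 150
      first_within_s: 150
      from: recognition

  - id: cd08_epinephrine_dose
    description_key: item.correct_epinephrine_dose
    reconstructed: false
    rule:
      kind: tap
      buttons: [prepare_epinephrine]
      payload_equals: {dose_correct: true}

  - id: cd09_epinephrine_dilution
    description_key: item.correct_epinephrine_dilution
    reconstructed: false
    rule:
      kind: tap
      buttons: [prepare_epinephrine]
      payload_equals: {dilution: "1:10000"}

  - id: cd10_first_epinephrine_timely
    description_key: item.first_epinephrine_within_5min
    reconstructed: false
    rule: {kind: tap, buttons: [administer_epinephrine], within_s: 300, from: recognition}

  - id: cd11_epinephrine_interval
    description_key: item.epinephrine_every_3_5min
    reconstructed: true
    rule:
      kind: interval_range
      buttons: [administer_epinephrine]
      min_gap_s: 150
      max_gap_s: 330

  - id: cd12_vascular_access
    description_key: item.vascular_access_obtained
    reconstructed: true
    rule: {kind: tap, buttons: [obtain_iv_access], within_s: 180, from: recognition}

  - id: cd13_reversible_causes_search
    description_key: item.reversible_causes_searched
    reconstructed: false
    rule: {kind: tap, buttons: [review_reversible_causes]}

  - id: cd14_hypovolemia_treatment
    description_key: item.hypovolemia_treated
    reconstructed: false
    rule: {kind: tap, buttons: [give_fluid_bolus]}

  - id: cd15_airway_management
    description_key: item.airway_managed
    reconstructed: true
    rule: {kind: tap, buttons: [maintain_bvm, advanced_airway]}

  - id: cd16_prompt_cpr_resumption
    description_key: item.cpr_resumed_promptly
    reconstructed: true
    rule:
      kind: resume_within
      buttons: [resume_compressions]
      within_s: 15
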