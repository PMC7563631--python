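# Clinical performance rubric, asystole section (reconstruction).
#
# Each task scores 0 (not performed), 1 (performed partially, incorrectly,
# or late) or 2 (performed completely, correctly and timely); the final
# task caps at 1.  Totals range 0-13.
#
# `presence` decides 0 vs >=1; `full` upgrades to the task maximum.

tasks:
  - id: cpt1_arrest_recognition
    description_key: task.recognize_arrest
    max_points: 2
    presence: {kind: tap, buttons: [recognize_ca]}
    full: {kind: tap, buttons: [recognize_ca], within_s: 60, from: start}

  - id: cpt2_cpr_initiation
    description_key: task.start_cpr
    max_points: 2
    presence: {kind: tap, buttons: [start_compressions]}
    full: {kind: tap, buttons: [start_compressions], within_s: 60, from: recognition}

  - id: cpt3_cpr_quality
    description_key: task.cpr_quality
    max_points: 2
    presence: {kind: tap, buttons: [set_cpr_ratio]}
    full:
      kind: all
      rules:
        - {kind: tap, buttons: [set_cpr_ratio], payload_equals: {ratio: "15:2"}}
        - {kind: tap, buttons: [start_compressions], payload_range: {rate_cpm: [100, 120]}}

  - id: cpt4_epinephrine_preparation
    description_key: task.epinephrine_preparation
    max_points: 2
    presence: {kind: tap, buttons: [prepare_epinephrine]}
    full:
      kind: tap
      buttons: [prepare_epinephrine]
      payload_equals: {dose_correct: true, dilution: "1:10000"}

  - id: cpt5_epinephrine_timing
    description_key: task.epinephrine_timing
    max_points: 2
    presence: {kind: tap, buttons: [administer_epinephrine]}
    full: {kind: tap, buttons: [administer_epinephrine], within_s: 300, from: recognition}

  - id: cpt6_reversible_causes
    description_key: task.reversible_causes
    max_points: 2
    presence: {kind: tap, buttons: [review_reversible_causes]}
    full:
      kind: all
      rules:
        - {kind: tap, buttons: [review_reversible_causes]}
        - {kind: tap, buttons: [give_fluid_bolus]}

  - id: cpt7_airway_management
    description_key: task.airway
    max_points: 1
    presence: {kind: tap, buttons: [maintain_bvm, advanced_airway]}
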