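# Default pediatric cardiac-arrest guidance flow.
#
# Reconstruction of a checklist-style PALS cognitive aid: an initial
# assessment screen, CPR initiation, a rhythm-identification screen that
# branches into nonshockable (epinephrine-first) and shockable
# (defibrillation) pathways, reversible-causes and airway screens, and a
# ROSC pathway.  Screen contents are a faithful functional reconstruction,
# not a pixel-level clone of any particular app.
#
# Button ids are stable tokens; label_key values are i18n identifiers.

start_node: initial_assessment

pathway_tags:
  initial_assessment: shared
  start_cpr: shared
  rhythm_check: shared
  resume_cpr: shared
  cpr_quality: shared
  rosc: shared
  case_end: shared
  resume_cpr_ns: nonshockable
  vascular_access: nonshockable
  epi_decision: nonshockable
  epi_preparation: nonshockable
  epi_administration: nonshockable
  reversible_causes: nonshockable
  airway_management: nonshockable
  defib_charge: shockable
  defib_shock: shockable

nodes:
  initial_assessment:
    advance_rule: ALL_SEQUENTIAL_TAPPED
    next: start_cpr
    buttons:
      - {id: check_responsiveness}
      - {id: call_help}
      - {id: recognize_ca, effect: ca_recognized}

  start_cpr:
    advance_rule: ALL_SEQUENTIAL_TAPPED
    next: rhythm_check
    buttons:
      - {id: start_compressions}
      - {id: set_cpr_ratio}
      - {id: attach_monitor}

  rhythm_check:
    rhythm_choice: true
    rhythm_edges:
      nonshockable: resume_cpr_ns
      shockable: defib_charge
      rosc: rosc

  # Immediately resume compressions after every rhythm check; the two
  # resume screens are identical but keep the pathway branch explicit.
  resume_cpr_ns:
    advance_rule: ALL_SEQUENTIAL_TAPPED
    next: vascular_access
    buttons:
      - {id: resume_compressions}

  defib_charge:
    advance_rule: ALL_SEQUENTIAL_TAPPED
    next: defib_shock
    buttons:
      - {id: charge_defibrillator}
      - {id: clear_patient}

  defib_shock:
    advance_rule: ALL_SEQUENTIAL_TAPPED
    next: resume_cpr
    buttons:
      - {id: deliver_shock, effect: shock_delivered}

  resume_cpr:
    advance_rule: ALL_SEQUENTIAL_TAPPED
    next: vascular_access
    buttons:
      - {id: resume_compressions}

  vascular_access:
    advance_rule: ONE_CHOICE_SELECTED
    choices:
      obtain_iv_access: epi_decision
      access_present: epi_decision
    buttons:
      - {id: obtain_iv_access, layout: ALTERNATIVE, kind: CHOICE}
      - {id: access_present, layout: ALTERNATIVE, kind: CHOICE, navigation: true}

  epi_decision:
    advance_rule: ONE_CHOICE_SELECTED
    choices:
      give_epinephrine: epi_preparation
      defer_epinephrine: reversible_causes
    buttons:
      - {id: give_epinephrine, layout: ALTERNATIVE, kind: CHOICE, navigation: true}
      - {id: defer_epinephrine, layout: ALTERNATIVE, kind: CHOICE, navigation: true}

  # Preparation and administration are deliberately separate screens.
  epi_preparation:
    advance_rule: ALL_SEQUENTIAL_TAPPED
    next: epi_administration
    compute_dose_for: epinephrine
    buttons:
      - {id: prepare_epinephrine}

  epi_administration:
    advance_rule: ALL_SEQUENTIAL_TAPPED
    next: reversible_causes
    buttons:
      - {id: administer_epinephrine, effect: epi_administered}
      - {id: flush_line}

  reversible_causes:
    advance_rule: ALL_SEQUENTIAL_TAPPED
    next: airway_management
    buttons:
      - {id: review_reversible_causes}
      - {id: give_fluid_bolus}

  airway_management:
    advance_rule: ONE_CHOICE_SELECTED
    choices:
      maintain_bvm: cpr_quality
      advanced_airway: cpr_quality
    buttons:
      - {id: maintain_bvm, layout: ALTERNATIVE, kind: CHOICE}
      - {id: advanced_airway, layout: ALTERNATIVE, kind: CHOICE}

  cpr_quality:
    advance_rule: ALL_SEQUENTIAL_TAPPED
    next: rhythm_check
    buttons:
      - {id: reassess_cpr_quality}

  rosc:
    advance_rule: ALL_SEQUENTIAL_TAPPED
    next: case_end
    buttons:
      - {id: reassess_patient}
      - {id: post_rosc_care}

  case_end: {}
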