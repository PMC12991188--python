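# Vignette archetype pool for the synthetic cohort simulator.
#
# Each archetype is a clinically coherent presentation: a complaint-filter
# category, a noiseless answer script through the default questionnaire,
# and the ground-truth acuity level the default rule table assigns to it
# (verified at load). Exactly three archetypes are emergency-class,
# mirroring the emergency presentations a small implementation cohort can
# be expected to contain; every acuity band and all four complaint
# categories are represented.
archetypes:
  # --- eye injury ---------------------------------------------------------
  - id: chemical_splash_injury
    category: injury
    level: EMERGENCY_SAME_DAY
    emergency_class: true
    script:
      - {question: q_filter, options: [injury]}
      - {question: q_injury_mechanism, options: [chemical]}
  - id: blunt_trauma_injury
    category: injury
    level: EMERGENCY_SAME_DAY
    emergency_class: true
    script:
      - {question: q_filter, options: [injury]}
      - {question: q_injury_mechanism, options: [blunt]}
  - id: minor_foreign_body
    category: injury
    level: SOON_48H
    emergency_class: false
    script:
      - {question: q_filter, options: [injury]}
      - {question: q_injury_mechanism, options: [minor]}
      - {question: q_injury_now, options: [red, gritty]}

  # --- red and/or painful eye ---------------------------------------------
  - id: acute_angle_closure
    category: red_painful
    level: EMERGENCY_SAME_DAY
    emergency_class: true
    script:
      - {question: q_filter, options: [red_painful]}
      - {question: q_pain, options: [severe]}
      - {question: q_systemic, options: [yes_nausea]}
      - {question: q_red_features, options: [red, light_hurts]}
  - id: contact_lens_keratitis
    category: red_painful
    level: URGENT_24H
    emergency_class: false
    script:
      - {question: q_filter, options: [red_painful]}
      - {question: q_pain, options: [moderate]}
      - {question: q_red_features, options: [red, light_hurts, contact_lenses]}
  - id: scleritis
    category: red_painful
    level: URGENT_24H
    emergency_class: false
    script:
      - {question: q_filter, options: [red_painful]}
      - {question: q_pain, options: [severe]}
      - {question: q_systemic, options: [no_nausea]}
      - {question: q_red_features, options: [red]}
  - id: viral_conjunctivitis
    category: red_painful
    level: SELF_CARE
    emergency_class: false
    script:
      - {question: q_filter, options: [red_painful]}
      - {question: q_pain, options: [gritty]}
      - {question: q_red_features, options: [discharge]}
  - id: episcleritis
    category: red_painful
    level: ROUTINE_WEEK
    emergency_class: false
    script:
      - {question: q_filter, options: [red_painful]}
      - {question: q_pain, options: [none]}
      - {question: q_red_features, options: [red]}

  # --- painless visual disturbance ------------------------------------------
  - id: retinal_detachment_warning
    category: visual_disturbance
    level: URGENT_24H
    emergency_class: false
    script:
      - {question: q_filter, options: [visual_disturbance]}
      - {question: q_vision, options: [flashes_floaters]}
  - id: sudden_vision_loss
    category: visual_disturbance
    level: URGENT_24H
    emergency_class: false
    script:
      - {question: q_filter, options: [visual_disturbance]}
      - {question: q_vision, options: [sudden_loss]}
  - id: progressive_cataract
    category: visual_disturbance
    level: ROUTINE_WEEK
    emergency_class: false
    script:
      - {question: q_filter, options: [visual_disturbance]}
      - {question: q_vision, options: [gradual]}

  # --- eyelid problems ------------------------------------------------------
  - id: chalazion
    category: eyelid
    level: ROUTINE_WEEK
    emergency_class: false
    script:
      - {question: q_filter, options: [eyelid]}
      - {question: q_lid, options: [lump]}
  - id: blepharitis
    category: eyelid
    level: SELF_CARE
    emergency_class: false
    script:
      - {question: q_filter, options: [eyelid]}
      - {question: q_lid, options: [itchy]}
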