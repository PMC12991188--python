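# Representative default questionnaire for the ophthalmic triage engine.
#
# This is a fixture, not a clone of any production instrument: the engine is
# content-agnostic, and this definition exercises the four complaint-filter
# categories, the trauma fast-path and every acuity class of the default
# rule table. Edges from a question are tried in declaration order; the
# last edge of each question is the mandatory unconditional default.
version: "default-1.0"

vocabulary:
  - chemical_splash
  - blunt_trauma
  - high_velocity_particle
  - foreign_body_sensation
  - severe_pain
  - moderate_pain
  - gritty_discomfort
  - nausea_vomiting
  - red_eye
  - photophobia
  - sticky_discharge
  - contact_lens_wear
  - sudden_vision_loss
  - new_flashes_floaters
  - sudden_double_vision
  - gradual_blur
  - lid_lump
  - itchy_lids

entry: q_filter

questions:
  - id: q_filter
    text: "Which of these best describes your main problem today?"
    select_mode: single
    options:
      - id: red_painful
        label: "Red and/or painful eye or eyes"
      - id: visual_disturbance
        label: "Painless visual disturbance"
      - id: eyelid
        label: "Eyelid problems"
      - id: injury
        label: "Eye injury"

  # --- eye injury branch -------------------------------------------------
  - id: q_injury_mechanism
    text: "How was the eye injured?"
    select_mode: single
    options:
      - id: chemical
        label: "A chemical, liquid or powder splashed into the eye"
        symptom_codes: [chemical_splash]
        trauma_flag: chemical
      - id: blunt
        label: "A blow to the eye (fist, ball, elbow...)"
        symptom_codes: [blunt_trauma]
        trauma_flag: blunt
      - id: high_velocity
        label: "A fast-moving particle hit the eye (grinding, hammering, strimming)"
        symptom_codes: [high_velocity_particle]
        trauma_flag: high_velocity
      - id: minor
        label: "Something minor went in (dust, eyelash, make-up)"
        symptom_codes: [foreign_body_sensation]

  - id: q_injury_now
    text: "How does the injured eye feel now?"
    select_mode: multiple
    options:
      - id: red
        label: "It looks red"
        symptom_codes: [red_eye]
      - id: gritty
        label: "It feels gritty or scratchy"
        symptom_codes: [gritty_discomfort]
      - id: settled
        label: "It has mostly settled"

  # --- red / painful branch ----------------------------------------------
  - id: q_pain
    text: "How bad is the pain?"
    select_mode: single
    options:
      - id: severe
        label: "Severe - deep ache, hard to carry on as normal"
        symptom_codes: [severe_pain]
      - id: moderate
        label: "Moderate - sore but bearable"
        symptom_codes: [moderate_pain]
      - id: gritty
        label: "Gritty, burning or itchy rather than painful"
        symptom_codes: [gritty_discomfort]
      - id: none
        label: "No real pain"

  - id: q_systemic
    text: "With the pain, do you also feel sick (nausea) or have you vomited?"
    select_mode: single
    options:
      - id: yes_nausea
        label: "Yes"
        symptom_codes: [nausea_vomiting]
      - id: no_nausea
        label: "No"

  - id: q_red_features
    text: "Tick everything that applies to the affected eye"
    select_mode: multiple
    options:
      - id: red
        label: "The white of the eye is red"
        symptom_codes: [red_eye]
      - id: light_hurts
        label: "Bright light hurts the eye"
        symptom_codes: [photophobia]
      - id: discharge
        label: "Sticky discharge or crusting"
        symptom_codes: [sticky_discharge]
      - id: contact_lenses
        label: "I wear contact lenses"
        symptom_codes: [contact_lens_wear]
      - id: none
        label: "None of these"

  # --- painless visual disturbance branch --------------------------------
  - id: q_vision
    text: "Which best describes the change in your vision?"
    select_mode: single
    options:
      - id: sudden_loss
        label: "Sudden loss or dimming of vision in one or both eyes"
        symptom_codes: [sudden_vision_loss]
      - id: flashes_floaters
        label: "New flashes of light or a shower of floaters"
        symptom_codes: [new_flashes_floaters]
      - id: double
        label: "Sudden double vision"
        symptom_codes: [sudden_double_vision]
      - id: gradual
        label: "Gradual blurring over weeks or months"
        symptom_codes: [gradual_blur]

  # --- eyelid branch ------------------------------------------------------
  - id: q_lid
    text: "What is the main problem with the eyelid?"
    select_mode: single
    options:
      - id: lump
        label: "A lump or swelling on the lid"
        symptom_codes: [lid_lump]
      - id: itchy
        label: "Itchy, flaky or sore lid edges"
        symptom_codes: [itchy_lids]
      - id: sticky
        label: "Sticky or crusted lashes"
        symptom_codes: [sticky_discharge]

edges:
  # filter routing
  - {from: q_filter, to: q_injury_mechanism, when: {question: q_filter, any_of: [injury]}}
  - {from: q_filter, to: q_pain,             when: {question: q_filter, any_of: [red_painful]}}
  - {from: q_filter, to: q_vision,           when: {question: q_filter, any_of: [visual_disturbance]}}
  - {from: q_filter, to: q_lid}

  # injury: potentially severe trauma fast-paths straight to TERMINAL
  - {from: q_injury_mechanism, to: TERMINAL,
     when: {question: q_injury_mechanism, any_of: [chemical, blunt, high_velocity]}}
  - {from: q_injury_mechanism, to: q_injury_now}
  - {from: q_injury_now, to: TERMINAL}

  # red / painful: severe pain asks about systemic upset first
  - {from: q_pain, to: q_systemic, when: {question: q_pain, any_of: [severe]}}
  - {from: q_pain, to: q_red_features}
  - {from: q_systemic, to: q_red_features}
  - {from: q_red_features, to: TERMINAL}

  # painless visual disturbance and eyelid branches terminate after one item
  - {from: q_vision, to: TERMINAL}
  - {from: q_lid, to: TERMINAL}
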