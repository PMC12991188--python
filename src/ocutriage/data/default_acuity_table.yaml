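# Default symptom acuity table.
#
# Encodes the standard UK symptom-based urgency bands for eye casualty
# triage: emergency-class presentations (chemical/blunt/high-velocity
# trauma, suspected acute angle closure) route same-day to ED/EEC; urgent
# presentations (sudden visual loss, new flashes/floaters, sudden diplopia,
# painful photophobic or contact-lens-associated red eye) within 24 h to
# hospital or MECS/CUES; lower bands to community optometry or pharmacist
# self-care. A best-effort, versioned fixture: the engine treats it as data.
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

rules:
  # --- emergency class (same-day hospital) -------------------------------
  - id: r_chemical_injury
    trigger: {any_of: [chemical_splash]}
    level: EMERGENCY_SAME_DAY
    service_hint: ED_EEC
    emergency_class: true
  - id: r_blunt_trauma
    trigger: {any_of: [blunt_trauma]}
    level: EMERGENCY_SAME_DAY
    service_hint: ED_EEC
    emergency_class: true
  - id: r_high_velocity
    trigger: {any_of: [high_velocity_particle]}
    level: EMERGENCY_SAME_DAY
    service_hint: ED_EEC
    emergency_class: true
  - id: r_angle_closure
    trigger: {all_of: [severe_pain, nausea_vomiting]}
    level: EMERGENCY_SAME_DAY
    service_hint: ED_EEC
    emergency_class: true

  # --- urgent (within 24 h, hospital or MECS/CUES) -----------------------
  - id: r_sudden_vision_loss
    trigger: {any_of: [sudden_vision_loss]}
    level: URGENT_24H
    service_hint: ED_EEC
  - id: r_flashes_floaters
    trigger: {any_of: [new_flashes_floaters]}
    level: URGENT_24H
    service_hint: MECS_CUES
  - id: r_sudden_diplopia
    trigger: {any_of: [sudden_double_vision]}
    level: URGENT_24H
    service_hint: ED_EEC
  - id: r_severe_pain
    trigger: {any_of: [severe_pain]}
    level: URGENT_24H
    service_hint: MECS_CUES
  - id: r_systemic_upset
    trigger: {any_of: [nausea_vomiting]}
    level: URGENT_24H
    service_hint: MECS_CUES
  - id: r_cl_red_eye
    trigger: {all_of: [red_eye, contact_lens_wear]}
    level: URGENT_24H
    service_hint: MECS_CUES
  - id: r_photophobic_red_eye
    trigger: {all_of: [red_eye, photophobia]}
    level: URGENT_24H
    service_hint: MECS_CUES

  # --- soon (within 48 h, community optometry) ---------------------------
  - id: r_foreign_body
    trigger: {any_of: [foreign_body_sensation]}
    level: SOON_48H
    service_hint: COMMUNITY_OPTOMETRY
  - id: r_moderate_pain
    trigger: {any_of: [moderate_pain]}
    level: SOON_48H
    service_hint: COMMUNITY_OPTOMETRY
  - id: r_photophobia_alone
    trigger: {any_of: [photophobia]}
    level: SOON_48H
    service_hint: COMMUNITY_OPTOMETRY

  # --- routine (within a week) -------------------------------------------
  - id: r_red_eye_alone
    trigger: {any_of: [red_eye]}
    level: ROUTINE_WEEK
    service_hint: COMMUNITY_OPTOMETRY
  - id: r_lid_lump
    trigger: {any_of: [lid_lump]}
    level: ROUTINE_WEEK
    service_hint: COMMUNITY_OPTOMETRY
  - id: r_gradual_blur
    trigger: {any_of: [gradual_blur]}
    level: ROUTINE_WEEK
    service_hint: COMMUNITY_OPTOMETRY

  # --- self care (pharmacist) --------------------------------------------
  - id: r_sticky_discharge
    trigger: {any_of: [sticky_discharge]}
    level: SELF_CARE
    service_hint: PHARMACIST
  - id: r_itchy_lids
    trigger: {any_of: [itchy_lids]}
    level: SELF_CARE
    service_hint: PHARMACIST
  - id: r_gritty
    trigger: {any_of: [gritty_discomfort]}
    level: SELF_CARE
    service_hint: PHARMACIST
  - id: r_contact_lens_advice
    trigger: {any_of: [contact_lens_wear]}
    level: SELF_CARE
    service_hint: PHARMACIST
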