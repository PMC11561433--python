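# Default annotation vocabulary for telecare call corpora.
# Topics: one predominant topic per utterance. Dialogue acts are grouped into
# reporting categories; multiple acts may attach to a single utterance.
topics:
  - introduction
  - identification
  - appointments
  - telemonitoring
  - general_education
  - customized_coaching
  - related_medical_experience
  - symptom_checking
  - vitals
  - medication_management
  - lifestyle_management
  - social_chatting
  - others

speakers:
  - nurse_telecarer
  - patient
  - caregiver
  - other

dialogue_acts:
  exchanging_information: [request_inform, inform]
  understanding_information: [acknowledge, request_clarification, request_confirmation]
  performing_action:
    - request_action
    - accept_action_implicit
    - accept_action_explicit
    - reject_action_implicit
    - reject_action_explicit
  evaluation_of_health_condition: [evaluate, evaluate_positive, evaluate_negative]
  social_emotional: [socio_emotional]
  incomplete_dialogue_act: [back_channel, fragment, stall]
  others: [others]

attributes:
  symptoms:
    - breathlessness
    - swelling
    - cough
    - dizziness
    - chest_pain
    - heartbeat_palpitations
    - bleeding
    - headache
  symptom_attributes: [location, frequency, extent, time, activity]
  lifestyle_attributes: [fluid_and_salt_intake, smoking, alcohol]
  vitals_attributes: [blood_pressure, weight]
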