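# Default 31-item mouse clinical frailty catalog.
#
# 29 ordinal items (scored 0 / 0.5 / 1) grouped by body system, plus two
# measured items (weight in grams, surface temperature in deg C) scored by
# |z| distance from a young-adult reference.  Substitute your lab's item
# names, reference statistics and bin maps here; pass the file to the CLI
# via --catalog.  ref_mean/ref_sd defaults are placeholders used by the
# cohort simulator.
items:
- name: alopecia
  system: integument
  mode: ordinal
- name: loss_of_fur_colour
  system: integument
  mode: ordinal
- name: dermatitis
  system: integument
  mode: ordinal
- name: loss_of_whiskers
  system: integument
  mode: ordinal
- name: coat_condition
  system: integument
  mode: ordinal
- name: tumours
  system: musculoskeletal
  mode: ordinal
- name: distended_abdomen
  system: musculoskeletal
  mode: ordinal
- name: kyphosis
  system: musculoskeletal
  mode: ordinal
- name: tail_stiffening
  system: musculoskeletal
  mode: ordinal
- name: gait_disorders
  system: musculoskeletal
  mode: ordinal
- name: tremor
  system: musculoskeletal
  mode: ordinal
- name: forelimb_grip_loss
  system: musculoskeletal
  mode: ordinal
- name: body_condition
  system: musculoskeletal
  mode: ordinal
- name: vestibular_disturbance
  system: vestibulocochlear_auditory
  mode: ordinal
- name: hearing_loss
  system: vestibulocochlear_auditory
  mode: ordinal
- name: cataracts
  system: ocular_nasal
  mode: ordinal
- name: corneal_opacity
  system: ocular_nasal
  mode: ordinal
- name: eye_discharge
  system: ocular_nasal
  mode: ordinal
- name: microphthalmia
  system: ocular_nasal
  mode: ordinal
- name: vision_loss
  system: ocular_nasal
  mode: ordinal
- name: menace_reflex_loss
  system: ocular_nasal
  mode: ordinal
- name: nasal_discharge
  system: ocular_nasal
  mode: ordinal
- name: malocclusions
  system: digestive_urogenital
  mode: ordinal
- name: rectal_prolapse
  system: digestive_urogenital
  mode: ordinal
- name: urogenital_prolapse
  system: digestive_urogenital
  mode: ordinal
- name: diarrhea
  system: digestive_urogenital
  mode: ordinal
- name: breathing_abnormality
  system: respiratory
  mode: ordinal
- name: mouse_grimace
  system: discomfort
  mode: ordinal
- name: piloerection
  system: discomfort
  mode: ordinal
- name: weight
  system: measured
  mode: z_binned
  ref_mean: 31.0
  ref_sd: 3.0
  bin_edges:
  - 1.0
  - 2.0
  - 3.0
  - 4.0
  bin_scores:
  - 0.0
  - 0.25
  - 0.5
  - 0.75
  - 1.0
- name: temperature
  system: measured
  mode: z_binned
  ref_mean: 36.5
  ref_sd: 0.5
  bin_edges:
  - 1.0
  - 2.0
  - 3.0
  - 4.0
  bin_scores:
  - 0.0
  - 0.25
  - 0.5
  - 0.75
  - 1.0
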