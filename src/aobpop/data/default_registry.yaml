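# Default receptive-field pattern registry for the canonical 11-stimulus panel.
#
# Basic patterns list a preferred stimulus set that must beat the rest of the
# panel (strict inequalities). Adjusted patterns list explicit per-strain or
# per-status conditions restricted to male stimuli; stimuli absent from a
# condition are irrelevant to it. Complementary patterns (~id, all
# inequalities reversed) are generated automatically, giving Bonferroni
# families of 16 (basic) and 12 (adjusted).
#
# The MALE pattern (all nine male stimuli stronger than both female stimuli)
# is the sex-category counterpart of FEMALE and completes the 8-pattern basic
# set; edit this file to audit or change the families.

auto_complement: true
groups:
  basic:
    - id: FEMALE
      preferred: [F_ICR_NON_EST, F_ICR_EST]
    - id: MALE
      preferred: [M_ICR_NAIVE, M_ICR_DOM, M_ICR_CAST,
                  M_BC_NAIVE, M_BC_DOM, M_BC_CAST,
                  M_C57_NAIVE, M_C57_DOM, M_C57_CAST]
    - id: MALE_ICR
      preferred: [M_ICR_NAIVE, M_ICR_DOM, M_ICR_CAST]
    - id: MALE_BC
      preferred: [M_BC_NAIVE, M_BC_DOM, M_BC_CAST]
    - id: MALE_C57
      preferred: [M_C57_NAIVE, M_C57_DOM, M_C57_CAST]
    - id: NAIVE
      preferred: [M_ICR_NAIVE, M_BC_NAIVE, M_C57_NAIVE]
    - id: DOM
      preferred: [M_ICR_DOM, M_BC_DOM, M_C57_DOM]
    - id: CAST
      preferred: [M_ICR_CAST, M_BC_CAST, M_C57_CAST]
  adjusted:
    - id: NAIVE_STRAIN
      conditions:
        - {preferred: [M_ICR_NAIVE], compared: [M_ICR_DOM, M_ICR_CAST]}
        - {preferred: [M_BC_NAIVE], compared: [M_BC_DOM, M_BC_CAST]}
        - {preferred: [M_C57_NAIVE], compared: [M_C57_DOM, M_C57_CAST]}
    - id: DOM_STRAIN
      conditions:
        - {preferred: [M_ICR_DOM], compared: [M_ICR_NAIVE, M_ICR_CAST]}
        - {preferred: [M_BC_DOM], compared: [M_BC_NAIVE, M_BC_CAST]}
        - {preferred: [M_C57_DOM], compared: [M_C57_NAIVE, M_C57_CAST]}
    - id: CAST_STRAIN
      conditions:
        - {preferred: [M_ICR_CAST], compared: [M_ICR_NAIVE, M_ICR_DOM]}
        - {preferred: [M_BC_CAST], compared: [M_BC_NAIVE, M_BC_DOM]}
        - {preferred: [M_C57_CAST], compared: [M_C57_NAIVE, M_C57_DOM]}
    - id: ICR_STATE
      conditions:
        - {preferred: [M_ICR_NAIVE], compared: [M_BC_NAIVE, M_C57_NAIVE]}
        - {preferred: [M_ICR_DOM], compared: [M_BC_DOM, M_C57_DOM]}
        - {preferred: [M_ICR_CAST], compared: [M_BC_CAST, M_C57_CAST]}
    - id: BC_STATE
      conditions:
        - {preferred: [M_BC_NAIVE], compared: [M_ICR_NAIVE, M_C57_NAIVE]}
        - {preferred: [M_BC_DOM], compared: [M_ICR_DOM, M_C57_DOM]}
        - {preferred: [M_BC_CAST], compared: [M_ICR_CAST, M_C57_CAST]}
    - id: C57_STATE
      conditions:
        - {preferred: [M_C57_NAIVE], compared: [M_ICR_NAIVE, M_BC_NAIVE]}
        - {preferred: [M_C57_DOM], compared: [M_ICR_DOM, M_BC_DOM]}
        - {preferred: [M_C57_CAST], compared: [M_ICR_CAST, M_BC_CAST]}
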