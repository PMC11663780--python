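# Default phrase bank for the synthetic clinical-note generator.
#
# Positive cues span the five kinds of evidence that make a section positive
# for cognitive decline: documented concerns, symptoms, diagnoses, cognitive
# assessments, and cognition-directed therapies.  Hard-negative cues mention
# cognition-related terms yet describe non-progressive situations (improving,
# transient, reversible, negated, or uncertain mentions) and therefore carry
# label 0.  Every cue phrase (positive and hard-negative) contains at least
# one expert-lexicon keyword, so keyword screening retains all of them;
# filler sentences contain none, so plain negatives are screened out.
# Users may edit or extend any list; invariants are re-checked at load time.
positive_cues:
  concern:
    - "Patient and family report growing memory concerns over the past year."
    - "Daughter is worried about increasing forgetfulness at home."
    - "Patient finds it difficult to recall names in conversation."
  symptom:
    - "Notable short term memory loss reported during the visit."
    - "Patient could not remember recent appointments or conversations."
    - "Episodes of disorientation to time and place were observed."
    - "Progressive word finding trouble noted in spontaneous speech."
  diagnosis:
    - "Assessment consistent with mild cognitive impairment."
    - "Diagnosis of early Alzheimer dementia was discussed with the family."
    - "Chart lists major neurocognitive disorder among active problems."
  assessment:
    - "Mini-Cog administered today; results raise concern for cognitive decline."
    - "MoCA score of 21 out of 30 obtained during today's evaluation."
    - "MMSE performed to assess cognition; patient performed below expected range."
  therapy:
    - "Referred for cognitive-linguistic therapy to address communication changes."
    - "Donepezil initiated for management of memory impairment."
hard_negative_cues:
  improvement:
    - "Cognitive function improvement noted since the last visit."
    - "Memory has improved markedly following treatment adjustment."
  transient:
    - "Temporary forgetfulness attributed to codeine started last week."
    - "Occasional memory lapses due to a recent medication change, expected to resolve."
  reversible:
    - "Brief confusion shortly after surgery, fully resolved before discharge."
    - "Transient disorientation following anesthesia, resolved within hours."
  negated:
    - "No evidence of memory loss or related concerns at this visit."
    - "Patient denies any decline in thinking or day-to-day abilities."
  uncertain:
    - "Possible subtle memory changes of uncertain significance; will monitor."
    - "Isolated report of misplacing items; unclear if this represents true decline."
filler_sentences:
  - "Blood pressure today measured 128 over 76 with a regular pulse."
  - "Patient continues home medications without reported side effects."
  - "Lungs clear to auscultation bilaterally with no wheezes or crackles."
  - "Follow up appointment scheduled in three months with primary care."
  - "Lipid panel reviewed and statin therapy continued at the current dose."
  - "Right knee pain improved with physical therapy over the last month."
  - "Influenza vaccination administered in the left deltoid without complication."
  - "Diet and regular walking were encouraged at today's visit."
  - "Skin warm and dry with no rashes or lesions observed."
  - "Renal panel within normal limits and hydration adequate."
  - "Patient reports good appetite and stable weight since the last visit."
  - "Cardiac rhythm regular without murmurs, rubs, or gallops."
  - "Hemoglobin A1c stable at 6.8 percent; continue the current regimen."
  - "Colonoscopy screening discussed and patient will consider scheduling."
  - "Ambulating independently without assistive devices."
  - "No chest pain, palpitations, or breathlessness reported."
  - "Hearing aids working well per patient report."
  - "Dose of lisinopril unchanged and potassium within the target range."
  - "Annual wellness visit completed with preventive measures reviewed."
  - "Mole on the left forearm unchanged in size and color."
  - "Gait steady with no falls reported since the previous appointment."
  - "Thyroid panel ordered to follow up on a prior borderline result."
  - "Patient tolerated the procedure well and returned to the recovery area."
  - "Dental cleaning completed last week without complications."
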