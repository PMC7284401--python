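# Platform-automated response templates, one full line per line.
# Matching is exact on the normalized (lower-cased, punctuation-stripped) line.
Patient has indicated there are no changes to medications.
Patient has indicated there are no changes to symptoms.
Patient has indicated there are no changes to their condition.
Patient has completed the weekly symptom survey.
Patient has updated their medication list.
This is an automated reminder to complete your survey.
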