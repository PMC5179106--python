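# Free-text development-stage synonyms, lowercased before lookup.
# Any unmapped stage beginning with "phase" is treated as clinical_trial;
# anything else falls back to experimental with a warning.
approved:
  - approved
  - fda approved
  - marketed
  - launched
  - registered
clinical_trial:
  - clinical trial
  - clinical
  - investigational
  - phase i
  - phase ii
  - phase iii
  - phase iv
  - phase i/ii
  - phase ii/iii
  - phase iii/iv
experimental:
  - experimental
  - terminated
  - withdrawn
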