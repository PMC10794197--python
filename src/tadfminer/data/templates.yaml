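# Sentence phrasing templates for the synthetic corpus generator.
# Placeholders: {compound}, {value}, {temp_clause}. Adding a phrasing here
# extends generator coverage without code changes.
sentence:
  lambda_em:
    - "The emission maximum of {compound} is at {value} nm."
    - "{compound} displays an emission maximum at {value} nm."
    - "The emission maximum of {compound} was found at {value} nm."
  plqy:
    - "The PLQY of {compound} is {value}%."
    - "{compound} shows a PLQY of {value}%."
    - "The photoluminescence quantum yield of {compound} was measured to be {value}%."
  delta_e_st:
    - "The ΔEST of {compound} was measured to be {value} eV."
    - "The singlet-triplet energy splitting of {compound} is {value} eV."
    - "{compound} has a ΔEST of {value} eV."
  tau_d:
    - "The delayed lifetime of {compound} is {value} μs{temp_clause}."
    - "{compound} exhibits a delayed lifetime of {value} μs{temp_clause}."
    - "The τd of {compound} was measured to be {value} μs{temp_clause}."

# Paragraph-context template exercising forward-looking resolution: the
# property sentence names no compound; the preceding sentence registers it.
resolution:
  plqy:
    - "{compound} films were cast from solution. The PLQY is {value}%."
  lambda_em:
    - "{compound} was doped into a host matrix. The emission maximum is at {value} nm."

distractor:
  - "All samples were dissolved in {solvent} prior to the measurements."
  - "Measurements were carried out under {solvent} where applicable."
  - "Spectra were recorded in {solvent} at ambient conditions."

abbreviation:
  - "{long} ({short}) was synthesized following the reported procedure."
  - "{long} ({short}) was obtained in good yield."
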