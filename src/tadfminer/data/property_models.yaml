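# Default property ontology: specifier surface forms are configuration, not
# code. Symbols are matched case-insensitively after homoglyph
# normalization; add variants here to extend coverage.
lambda_em:
  dimension: length
  standard_unit: nm
  specifiers:
    - "λem"
    - "λEM"
    - "λmax(em)"
    - "λmax,em"
    - "λPL"
    - "emission maximum"
    - "maximum emission wavelength"
    - "emission peak"
    - "emission wavelength"
  extra_fields: [phase]

plqy:
  dimension: dimensionless-fraction
  standard_unit: "%"
  specifiers:
    - "ΦPL"
    - "PLQY"
    - "Φf"
    - "photoluminescence quantum yield"
    - "quantum yield"
  extra_fields: [phase, atmosphere]

delta_e_st:
  dimension: energy
  standard_unit: eV
  specifiers:
    - "ΔEST"
    - "ΔEst"
    - "ΔE(S1-T1)"
    - "ΔE(S1−T1)"
    - "singlet-triplet energy splitting"
    - "singlet-triplet splitting"
    - "singlet-triplet gap"
    - "singlet–triplet energy splitting"
  extra_fields: [is_experimental]

tau_d:
  dimension: time
  standard_unit: "μs"
  specifiers:
    - "τd"
    - "τD"
    - "τdelayed"
    - "delayed lifetime"
    - "delayed fluorescence lifetime"
    - "delayed-fluorescence lifetime"
  extra_fields: [temperature]
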