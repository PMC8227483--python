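# ICRP Publication 103 tissue weighting factors, female remainder list.
# Organ keys match the per-case dose-report column names.
weights:
  rbm: 0.12
  colon: 0.12
  lungs: 0.12
  stomach: 0.12
  breasts: 0.12
  gonads: 0.08
  urinary_bladder: 0.04
  oesophagus: 0.04
  liver: 0.04
  thyroid: 0.04
  bones: 0.01          # bone surface, reported as the "bones" dose
  brain: 0.01
  salivary_glands: 0.01
  skin: 0.01
remainder_weight: 0.12
remainder:
  - adrenals
  - extrathoracic
  - gall_bladder
  - heart
  - kidneys
  - lymphatic_nodes
  - muscle
  - oral_mucosa
  - pancreas
  - small_intestine
  - spleen
  - thymus
  - uterus
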