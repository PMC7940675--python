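name: aiwbo_apoe4
description: >
  Alzheimer's disease variant of the wild-type organoid cocktail: APOE4
  locked ON (duplication / gain-of-function) and amyloid-beta clearance
  locked OFF to represent the allele's inhibitory effect; otherwise
  identical to the wild-type protocol.
extends: aiwbo_wt
locked_on:
  - APOE4
locked_off:
  - AmyloidBetaClearance
profiles:
  - neural_cell_types
  - rostral_caudal_regions
  - ventral_dorsal_regions
  - cerebral_cortical_layers
  - cerebellar_cortical_layers
  - microcirculation
  - blood_brain_barrier
  - acid_base_status
  - alzheimers_features
  - cell_stress_features
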