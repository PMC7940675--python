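name: whole_organoid
description: >
  The combined whole-organoid validation panel (N = 55): 48 elements of the
  organoid pattern (cell types, regions, layers, microcirculation, barrier,
  stress markers) plus the 7 acid-base status concepts.
includes:
  - neural_cell_types
  - rostral_caudal_regions
  - ventral_dorsal_regions
  - cerebral_cortical_layers
  - cerebellar_cortical_layers
  - microcirculation
  - blood_brain_barrier
  - cell_stress_features
  - acid_base_status
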