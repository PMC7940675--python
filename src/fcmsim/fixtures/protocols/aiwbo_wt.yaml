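name: aiwbo_wt
description: >
  Unguided pluripotent-to-whole-brain-organoid differentiation cocktail:
  the four reprogramming transcription factors ON, a simulated B27 neural
  medium with zinc and doxycycline, and an optimised slow-rotating bioreactor
  environment (21% O2, 5% CO2, glucose, 37 C, high shear forces OFF).
  Age is fixed at 65 years on the [-1, +1] AGE scale.
age_years: 65
locked_on:
  # reprogramming transcription factors
  - OCT4
  - cMYC
  - KLF4
  - SOX2
  # B27 neural media components
  - Biotin
  - AminoAcids
  - Ascorbate
  - Catalase
  - Cortisol
  - FGF2
  - Glutathione
  - Albumin
  - Insulin
  - SOD1
  - SOD2
  - Progesterone
  - Retinol
  - ThyroidHormones
  - Transferrin
  - VitE
  - LCarnitine
  # supplements
  - Zinc
  - Doxycycline
  # bioreactor environment
  - CO2_5pct
  - O2_21pct
  - Glucose
  - Temp_37C
locked_off:
  - HighShearForces
profiles:
  - neural_cell_types
  - rostral_caudal_regions
  - ventral_dorsal_regions
  - cerebral_cortical_layers
  - cerebellar_cortical_layers
  - microcirculation
  - blood_brain_barrier
  - acid_base_status
  - cell_stress_features
metadata:
  # the AGE input's own composition in the knowledge base; descriptive only
  age_input_factors: {n_inputs: 57, n_positive_inputs: 29, n_negative_inputs: 28}
  environment:
    O2_21pct: "ambient oxygen 21%"
    CO2_5pct: "carbon dioxide 5%"
    Temp_37C: "temperature 37 degrees C"
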