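name: cell_stress_features
description: >
  Six-feature cell stress and neuronal cell death profile with the published
  signed input compositions (negative inputs inhibit, positive promote).
features:
  - {id: Glycolysis, expected: up,
     n_inputs: 51, n_negative_inputs: 19, n_positive_inputs: 32}
  - {id: PGK1, expected: up,
     n_inputs: 6, n_negative_inputs: 0, n_positive_inputs: 6}
  - {id: ER_Stress, expected: up,
     n_inputs: 84, n_negative_inputs: 29, n_positive_inputs: 55}
  - {id: ARCN1, expected: up,
     n_inputs: 1, n_negative_inputs: 0, n_positive_inputs: 1}
  - {id: GORASP2, expected: up,
     n_inputs: 1, n_negative_inputs: 0, n_positive_inputs: 1}
  - {id: NeuronCellDeath, label: "Neuron cell death", expected: up,
     n_inputs: 43, n_negative_inputs: 10, n_positive_inputs: 33}
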