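name: cerebellar_cortical_layers
description: >
  The four main layers of the cerebellar cortex, outer to inner.
features:
  - {id: CerebellarLayer1, expected: up}
  - {id: CerebellarLayer2, expected: up}
  - {id: CerebellarLayer3, expected: up}
  - {id: CerebellarLayer4, expected: up}
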