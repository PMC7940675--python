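name: cerebral_cortical_layers
description: >
  The six horizontal layers of the cerebral cortex, outer (Layer 1) to
  inner (Layer 6).
features:
  - {id: CerebralLayer1, expected: up}
  - {id: CerebralLayer2, expected: up}
  - {id: CerebralLayer3, expected: up}
  - {id: CerebralLayer4, expected: up}
  - {id: CerebralLayer5, expected: up}
  - {id: CerebralLayer6, expected: up}
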