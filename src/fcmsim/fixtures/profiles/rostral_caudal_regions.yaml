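name: rostral_caudal_regions
description: >
  The three rostral-caudal brain regions represented in a whole-brain
  organoid (the spinal cord is not simulated).
features:
  - {id: Forebrain, expected: up}
  - {id: Midbrain, expected: up}
  - {id: Hindbrain, expected: up}
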