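name: ventral_dorsal_regions
description: >
  Seven ventral (anterior) - dorsal (posterior) regional elements of the
  organoid. Individual element ids are package-invented (the source panel is
  not enumerated in print); the panel size and directions are what matter.
features:
  - {id: VentralForebrain, expected: up}
  - {id: DorsalForebrain, expected: up}
  - {id: VentralMidbrain, expected: up}
  - {id: DorsalMidbrain, expected: up}
  - {id: VentralHindbrain, expected: up}
  - {id: DorsalHindbrain, expected: up}
  - {id: VentralDorsalPatterning, expected: up}
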