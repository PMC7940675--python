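name: blood_brain_barrier
description: >
  Six concepts representative of a rudimentary blood-brain barrier: the
  barrier itself and its function, its astrocyte and pericyte components,
  tight junctions and basement membrane.
features:
  - {id: BBB, expected: up}
  - {id: BBBFunction, expected: up}
  - {id: BBBAstrocyteComponent, expected: up}
  - {id: BBBPericyteComponent, expected: up}
  - {id: TightJunctions, expected: up}
  - {id: BasementMembrane, expected: up}
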