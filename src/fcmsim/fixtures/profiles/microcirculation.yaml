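name: microcirculation
description: >
  Seven elements of a rudimentary organoid microcirculation (arterial,
  venous, capillary and lymphatic endothelial components, pericyte coverage,
  angiogenesis, intracellular oxygenation). Element ids beyond those named in
  prose are package-invented; panel size and directions are what matter.
features:
  - {id: EndothelialArterial, expected: up}
  - {id: EndothelialVenous, expected: up}
  - {id: EndothelialCapillary, expected: up}
  - {id: Lymphatics, expected: up}
  - {id: Angiogenesis, expected: up}
  - {id: PericyteCoverage, expected: up}
  - {id: IntracellularO2, expected: up}
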