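name: neural_cell_types
description: >
  The nine neural cell types commonly found in human brain organoids:
  neural precursors of the radial glial layer, neurons, glia, interneurons,
  microglia and the two vascular cell types of the blood-brain barrier.
  Expected present (up) in a differentiated whole-brain organoid.
features:
  - {id: RadialGlia_NSC, label: "Neural precursor cells (NPC/NSC, radial glia)", expected: up}
  - {id: Neurons, label: "Neurons", expected: up}
  - {id: Astrocytes, label: "Astrocytes", expected: up}
  - {id: OPC, label: "Oligodendrocyte precursor cells", expected: up}
  - {id: Oligodendrocytes, label: "Oligodendrocytes", expected: up}
  - {id: Interneurons, label: "Interneurons", expected: up}
  - {id: Microglia, label: "Microglial cells", expected: up}
  - {id: EndothelialCells, label: "Endothelial cells", expected: up}
  - {id: Pericytes, label: "Pericytes", expected: up}
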