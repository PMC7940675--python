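name: acid_base_status
description: >
  Seven phenotypic concepts whose joint expression indicates a mixed
  (compensated) metabolic alkalosis and respiratory acidosis: high
  bicarbonate and CO2, near-baseline intracellular H+, adequate oxygenation.
  Element ids beyond those named in prose are package-invented.
features:
  - {id: IntracellularHCO3, expected: up}
  - {id: IntracellularCO2, expected: up}
  - {id: IntracellularH, expected: up}
  - {id: IntracellularO2Content, expected: up}
  - {id: MetabolicAlkalosis, expected: up}
  - {id: RespiratoryAcidosis, expected: up}
  - {id: AcidBaseCompensation, expected: up}
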