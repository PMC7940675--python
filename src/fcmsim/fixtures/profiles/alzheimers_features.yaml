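name: alzheimers_features
description: >
  Ten-feature literature-derived Alzheimer's disease profile. Each feature
  records the published signed composition of its inputs in the knowledge
  base (negative inputs inhibit the feature, positive inputs promote it).
features:
  - {id: AmyloidBetaPlaques, label: "Amyloid beta plaques", expected: up,
     n_inputs: 9, n_negative_inputs: 3, n_positive_inputs: 6}
  - {id: AmyloidBetaClearance, label: "Amyloid beta protein (42/40) clearance", expected: up,
     n_inputs: 51, n_negative_inputs: 23, n_positive_inputs: 28}
  - {id: AmyloidBetaProtein_42_40, label: "Amyloid beta protein (Ab1-42/Ab1-40)", expected: up,
     n_inputs: 47, n_negative_inputs: 24, n_positive_inputs: 23}
  - {id: AmyloidBetaOligomers, label: "Amyloid-beta-oligomers/aggregation", expected: up,
     n_inputs: 45, n_negative_inputs: 23, n_positive_inputs: 22}
  - {id: APOE4, label: "ApoE4 (>ApoE3)", expected: up,
     n_inputs: 17, n_negative_inputs: 8, n_positive_inputs: 9}
  - {id: APP, label: "APP/amyloid precursor protein", expected: up,
     n_inputs: 50, n_negative_inputs: 24, n_positive_inputs: 26}
  - {id: NFTs, label: "NFTs/neurofibrillary tangles", expected: up,
     n_inputs: 10, n_negative_inputs: 4, n_positive_inputs: 6}
  - {id: TauProteins_MAPT, label: "Tau proteins/MAPT", expected: up,
     n_inputs: 27, n_negative_inputs: 16, n_positive_inputs: 11}
  - {id: TauProteinPhosphorylated, label: "Tau protein phosphorylated", expected: up,
     n_inputs: 52, n_negative_inputs: 25, n_positive_inputs: 27}
  - {id: TauProteinAggregation, label: "Tau protein aggregation", expected: up,
     n_inputs: 10, n_negative_inputs: 3, n_positive_inputs: 7}
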