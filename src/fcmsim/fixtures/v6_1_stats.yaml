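name: v6_1_stats
description: >
  Printed summary statistics of the v6.1 release of the proprietary
  knowledge base that the synthetic generator emulates: 4,516 gene/protein
  or phenotypic concepts, 41,493 non-zero signed relationships with a 0.656
  positive fraction, hence mean in/out degree 41493/4516 = 9.188 (> 9).
  The prior v5.0 release held 4,206 concepts and 37,223 relationships, so
  the upgrade added 4,270 relationships.
n_concepts: 4516
n_relationships: 41493
positive_fraction: 0.656
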