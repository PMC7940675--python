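"""Compare wild-type and disease conditions with exact Mann-Whitney tests.

The disease condition is the same designed network with every cell-type
input weight dampened to a quarter, mimicking a broad decline in cell-type
expression.  Per-concept 3-vs-3 exact tests bottom out at p = 0.1 (the
exact-test floor for triplicates), so a pooled-panel comparison is also
shown, which can reach conventional significance.
"""

from fcmsim import (
    Relationship,
    SimulationConfig,
    compare_conditions,
    designed_outcome_network,
    packaged_profile,
    run_replicates,
)

profile = packaged_profile("neural_cell_types")
net, clamps = designed_outcome_network(
    profile, {f: "up" for f in profile.feature_ids()}, seed=1
)

disease = net.copy()
for r in net.relationships:
    if r.target in profile.feature_ids():
        disease.remove_edges_into(r.target)
        disease.add_relationship(Relationship(r.source, r.target, r.weight * 0.25))

config = SimulationConfig(init_mode="uniform_random", seed=1, replicates=3)
wt = run_replicates(net, clamps, config)
dz = run_replicates(disease, clamps, config)

print("per-concept exact tests (n = 3 vs 3):")
for c in compare_conditions(wt, dz, profile.feature_ids(), pooling="per_concept"):
    print(f"  {c.concept_id:18s} U={c.U:4.1f} p={c.p_two_sided:.3f} "
          f"[{c.significant_at}]")

(pooled,) = compare_conditions(wt, dz, profile.feature_ids(),
                               pooling="pooled_panel")
print(f"pooled panel (27 vs 27 values): p={pooled.p_two_sided:.2e} "
      f"[{pooled.significant_at}]")
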