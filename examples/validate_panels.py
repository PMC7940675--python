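"""Score a simulated steady state against the literature panels.

Runs the designed-outcome organoid simulation and applies the
bias-compensated binomial test to each validation panel with the pretest
probability 0.656: the p-value is the chance that a panel of that size
agrees entirely by luck given the network's bias toward positive
predictions.  Small panels cannot reach significance (N=3 -> 0.282); the
combined 55-feature panel is essentially impossible to hit by chance.
"""

from fcmsim import (
    SimulationConfig,
    biased_binomial_test,
    designed_outcome_network,
    evaluate_profile,
    packaged_profile,
    run_replicates,
)

P_POS = 0.656
PANELS = [
    "rostral_caudal_regions",
    "cerebellar_cortical_layers",
    "cerebral_cortical_layers",
    "ventral_dorsal_regions",
    "neural_cell_types",
    "alzheimers_features",
    "whole_organoid",
]

organoid = packaged_profile("whole_organoid") + packaged_profile("alzheimers_features")
net, clamps = designed_outcome_network(
    organoid, {f: "up" for f in organoid.feature_ids()}, seed=1
)
summary = run_replicates(net, clamps,
                         SimulationConfig(init_mode="uniform_random", seed=1))

for name in PANELS:
    profile = packaged_profile(name)
    outcomes = evaluate_profile(summary, profile)
    res = biased_binomial_test(outcomes, p_pos=P_POS, panel=name)
    print(f"{name:28s} N={res.n_predictions:2d} agree={res.n_agree:2d} "
          f"p={res.p_value_printed}")
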