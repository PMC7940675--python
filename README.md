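# fcmsim

Fuzzy-cognitive-map simulation of clamped signed concept networks, built to
study in-silico organoid differentiation experiments: a knowledge graph of
gene/protein, phenotype and environment concepts is iterated under an
experimental "cocktail" of clamped inputs until it reaches a system-wide
steady state, and the steady state is scored against literature-derived
feature panels with a bias-compensated exact binomial test.

The package is aimed at computational biologists who want a transparent,
fully reproducible version of this workflow.  The knowledge base behind the
published whole-brain-organoid simulations is proprietary, so `fcmsim`
ships a synthetic generator that reproduces its printed summary statistics
(4,516 concepts; 41,493 signed relationships of which 65.6% are positive;
mean in/out degree 9.188) and the published per-feature input compositions,
plus designed-outcome networks whose steady-state signs are known
analytically, so the whole pipeline can be exercised end to end with ground
truth.

## Model

A concept network is a directed graph with signed weights
w<sub>ij</sub> ∈ [−1, +1] \ {0} (the influence of concept *j* on concept
*i*).  Activations x ∈ [−1, +1]<sup>n</sup> start at the zero baseline and
evolve synchronously as

x<sub>i</sub>(t+1) = tanh( Σ<sub>j</sub> w<sub>ij</sub> x<sub>j</sub>(t) ),

with clamped concepts — locked ON (+1), locked OFF (−1), or fixed (e.g. the
AGE input, where −1 is birth, 0 is 50 years and +1 is ≥ 100 years) — reset
to their clamp value after every step.  Convergence is declared when the
max-norm change stays below a tolerance (default 1e−6) for three
consecutive steps; iteration continues to the horizon (default 1000) and
any later departure from the recorded steady state is flagged as
"overtraining" (a limit cycle or divergence).  Experiments run in seeded
triplicate; replicate variability comes only from the random initialisation
of unclamped concepts, and per-concept means carry 95% t-based confidence
intervals.

Validation uses the network's sign bias: a chance prediction is positive
with pretest probability p<sub>pos</sub> = n<sub>positive</sub>/n<sub>edges</sub>
(0.656 for the emulated knowledge base) and negative with
p<sub>neg</sub> = 1 − p<sub>pos</sub>.  For a panel of N directional
predictions the p-value is the exact Poisson-binomial upper tail of the
agreement count under those per-prediction chance probabilities — for an
all-up, all-agree panel simply p<sub>pos</sub><sup>N</sup>.  Between-condition
comparisons use an exact two-sided Mann-Whitney U test (full enumeration up
to 12 pooled values, midrank ties included; tie-corrected normal
approximation above that, flagged as approximate).

## Worked example

```sh
python examples/validate_panels.py
```

builds a designed-outcome network in which all 55 organoid features and the
10 disease features are wired to come out expressed, simulates it in
triplicate under the clamped driver, and scores each packaged panel:

```
rostral_caudal_regions       N= 3 agree= 3 p=0.282
cerebellar_cortical_layers   N= 4 agree= 4 p=0.185
cerebral_cortical_layers     N= 6 agree= 6 p=0.080
ventral_dorsal_regions       N= 7 agree= 7 p=0.052
neural_cell_types            N= 9 agree= 9 p=0.022
alzheimers_features          N=10 agree=10 p=0.015
whole_organoid               N=55 agree=55 p=<0.00000001
```

Each line reads: the panel's N features all agreed with their expected
direction, and p is the exact chance of that full agreement under the
0.656-biased null — small panels can agree by luck (p = 0.282 for three
features), the combined 55-feature panel cannot.

Other examples: `generate_synthetic_network.py` (the emulated knowledge-base
statistics), `simulate_organoid_protocol.py` (the packaged wild-type
cocktail: reprogramming factors, B27 media, bioreactor environment, AGE at
65 years → 0.3), and `compare_wt_vs_disease.py` (exact per-concept
Mann-Whitney tests bottoming out at p = 0.1 for triplicates vs a pooled
panel reaching p < 0.001).

The same workflow is available from the shell:

```sh
fcmsim generate --spec src/fcmsim/fixtures/v6_1_stats.yaml --out net.tsv --seed 1
fcmsim demo --outdir demo_out --seed 1
fcmsim simulate --config run.yaml
fcmsim validate --summary demo_out/wt_summary.csv --profile neural_cell_types
fcmsim compare --summary-a demo_out/wt_summary.csv --summary-b demo_out/ad_summary.csv --profile neural_cell_types
```

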