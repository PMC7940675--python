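# Methods

## The simulation model

`fcmsim` iterates a fuzzy cognitive map: a directed graph of concepts
(genes/proteins, phenotypic features, environmental inputs) with signed
weights w_ij ∈ [−1, +1] excluding 0, under the synchronous update

    x_i(t+1) = squash( Σ_j w_ij · x_j(t) )

with `tanh` as the default squashing function and a bipolar sigmoid
(2/(1+e^−x) − 1 = tanh(x/2)) as an alternative.  The published platform this
design follows describes itself only as a hybrid of recurrent networks and
cognitive maps without stating its update rule, squash or stopping rule, so
these are this package's own choices: `tanh` because reported activations
span the full [−1, +1] scale; a synchronous update with no self-memory term
because it is the simplest member of the family and keeps the DAG
forward-evaluation oracle exact; hard post-squash clamping because locked-ON
cocktail components must never decay.  Consequences worth knowing:

* **Range preservation** is automatic (tanh maps into (−1, 1); clamps are
  in [−1, +1]).
* **Odd symmetry**: because tanh is odd, negating the clamps (and the
  initial state) while keeping the weights negates the entire trajectory.
  Note that negating *both* weights and clamps is not a symmetry — the two
  sign flips cancel on any concept driven by clamped inputs — so the
  clamp-only form is the invariant tested.
* **Contraction**: if every concept's absolute incoming-weight sum is below
  1 the map is a max-norm contraction and convergence is guaranteed; the
  designed-outcome generator uses this to build fixtures that provably
  converge.
* **Zero is absorbing for unforced concepts**: a concept with no inputs and
  no clamp relaxes to tanh(0) = 0, the baseline.

## Convergence and "overtraining"

Convergence: max per-concept change < `tolerance` (default 1e−6) for
`consecutive_stable_steps` (default 3) consecutive steps; the first such
iteration and state are recorded.  Iteration then *continues* to
`max_iterations` (default 1000, the published horizon) and any later
departure of at least `tolerance` from the recorded steady state sets the
`overtraining_detected` flag — this operationalises "no evidence of
overtraining after 1,000 iterations" as the absence of post-convergence
drift, catching limit cycles that momentarily slow below tolerance.  The
published iteration counts (45 wild-type, 42 disease) are properties of the
proprietary network and are not reproducible here; nothing in the package
asserts them.

Replicates (default 3, matching triplicate experiments) differ only through
the initial values of unclamped concepts, drawn uniformly from
[−ε, +ε] (ε = 0.1) with the substream `SeedSequence([seed, replicate])` —
the only unforced degree of freedom in the model, and therefore the
attributed source of the published replicate variance, which is never
explained in print.  A `zeros` mode gives fully deterministic runs.
Per-concept summaries are means with two-sided t-based 95% CIs
(df = replicates − 1); identical replicates give exact zero-width intervals.

## The bias-compensated panel test

The network's edge-sign composition biases chance predictions: p_pos =
n_positive/n_relationships (0.656 in the emulated knowledge base, so p_neg
= 0.344).  For a panel of N directional predictions, each prediction's
chance-success probability is p_pos if its predicted direction is up and
p_neg if down (a null prediction — exact-zero activation — never agrees
and takes its expected direction's probability so the null model stays
defined).  The p-value is the exact upper tail P(X ≥ observed agreements)
of the Poisson-binomial success count, computed by O(N²) convolution; for a
homogeneous all-up all-agree panel it reduces to p_pos^N.  The upper-tail
definition matches every published panel value (0.282 for N = 3, 0.185 for
N = 4, 0.08 for N = 6 at two decimals, 0.052 for N = 7, 0.015 for N = 10,
< 1e−8 for N = 55).  Two printed values are arithmetically inconsistent
with their stated panel sizes and are recorded rather than patched: the
nine-feature panel prints 0.023 where 0.656⁹ = 0.0225 (this package prints
0.022), and one six-feature panel prints 0.185, which is 0.656⁴.
Printed renderings use round-half-even at three decimals (two where the
source prints two); full precision is always retained alongside.  No
multiple-testing correction is applied, matching the source analysis.

## Mann-Whitney comparisons

Between-condition tests use the Mann-Whitney U statistic on midranks.  For
pooled sizes ≤ 12 the two-sided p is exact: all C(n_a+n_b, n_a) group
reassignments of the observed data are enumerated and p = P(|U − n_a·n_b/2|
≥ |U_obs − n_a·n_b/2|), which handles ties without approximation.  Larger
samples use scipy's tie-corrected normal approximation and are flagged
`exact=False`.  An exact 3-vs-3 test cannot fall below p = 0.1 (2 of 20
splits), so published per-concept p < 0.01 claims from triplicates cannot
arise from this test per concept; since the published pooling scheme is
unknown, both modes are provided — `per_concept` (honest triplicate floor)
and `pooled_panel` (all panel concepts' replicate values pooled per
condition, which can reach conventional significance).  Significance is
also rendered in the reporting buckets ns / p<0.05 / p<0.01 / p<0.001.

## The synthetic generator

The generator emulates only the printed statistics of the proprietary
knowledge base — it makes no claim of biological realism.  Given a spec
(n_concepts, n_relationships, positive_fraction, seed) it samples exactly
n_relationships distinct ordered pairs (self-loops excluded; uniform by
default, a lognormal-propensity "configuration" mode for heavier-tailed
degrees), assigns exactly round(positive_fraction · n_relationships)
positive signs, and draws magnitudes uniformly from [0.2, 1.0] — the source
reports signs only, and the lower bound keeps edges numerically alive.  The
packaged `v6_1_stats` spec encodes 4,516 concepts, 41,493 relationships and
positive fraction 0.656 (hence 27,219 positive edges and mean in/out degree
9.188); the prior release held 4,206 / 37,223, an upgrade of 4,270
relationships.  `embed_feature_nodes` rewires named feature nodes to carry
exactly their published signed input compositions (e.g. ER stress: 84
inputs = 29 negative + 55 positive; phosphorylated tau: 52 = 25 + 27),
replacing existing inbound edges and touching nothing else.

`designed_outcome_network` builds ground truth for end-to-end tests: a
clamped driver feeds one relay per feature, the relay feeds the feature
with a weight signed by the assigned direction, so the steady-state
activation is tanh(±w₂·tanh(w₁)) with a known sign, the network is acyclic
and contractive, and flipping one assignment flips exactly one edge.

## What the synthetic fixtures do and do not show

Passing tests demonstrate that the machinery is correct: the update rule,
convergence and overtraining logic, the exact statistics, and that the
generator hits the published counts and compositions exactly.  They do not
— and cannot — validate the biological content of the proprietary
knowledge base: synthetic topology is random, feature directions in
designed networks are assigned, and the published figure-level activations
and iteration counts depend on edges this package does not have.  The
packaged protocol fixtures (wild-type cocktail; disease variant = wild type
plus APOE4 locked ON and amyloid-beta clearance locked OFF) and the panel
fixtures (sizes 9/3/7/6/4/7/6/7 plus the 10-feature disease and 6-feature
stress panels; combined organoid panel N = 55) carry the published
structure so that real edge lists, if available, drop straight in.  Panels
whose member concepts are not enumerated in print carry package-invented
ids; the two tabulated profiles carry the published compositions verbatim.
One tabulated row ("Age … 57 input factors, 29 positive, 28 negative") is
kept as protocol metadata only, since it is unclear what it attaches to.

## Numerical and interface choices

* Problem sizes in tests and examples are kept small (networks of ≤ 300
  nodes except the single v6.1-statistics generation; 40–300 iteration
  horizons) — the model's properties are size-independent and the designed
  fixtures converge in under ten iterations.
* TSV/CSV weights are serialised with `repr` and re-read with
  correctly-rounded parsing, so round trips are bit-exact.
* Degenerate inputs fail loudly: zero or out-of-range weights, duplicate
  edges, unknown clamp targets, conflicting clamp entries, empty panels and
  empty protocol files are all validation errors, never silent fixes.
* The AGE scale interpolates linearly between its three published anchors
  (−1 at birth, 0 at 50, +1 at ≥ 100 years); ages above 100 saturate at +1
  and negative ages are errors.
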