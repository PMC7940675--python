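"""Synthetic knowledge-graph generator.

The proprietary knowledge base behind the published organoid simulations is
not available; this module generates networks that reproduce its printed
summary statistics exactly (concept count, relationship count, positive-edge
fraction, mean degree) and can embed feature nodes with the published signed
input compositions.  It makes no claim of biological realism — topology is
random, only the summary statistics are emulated.

It also builds small designed-outcome networks: acyclic, contractive
networks whose steady-state feature signs are known by construction, giving
the simulate -> evaluate -> validate pipeline a ground-truth end-to-end test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .network import Category, Concept, ConceptNetwork, Relationship
from .protocols import FeatureProfile
from .simulator import ClampSpec

__all__ = [
    "GeneratorSpec",
    "generate_network",
    "embed_feature_nodes",
    "designed_outcome_network",
    "v6_1_spec",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Target statistics for a synthetic network.

    Exactly ``round(positive_fraction * n_relationships)`` edges come out
    positive; weight magnitudes are uniform in ``weight_magnitude_range``
    (default [0.2, 1.0]; the lower bound avoids numerically dead edges, the
    printed statistics constrain signs only).  Self-loops are excluded.
    """

    n_concepts: int
    n_relationships: int
    positive_fraction: float = 0.5
    degree_model: str = "uniform_random"
    weight_magnitude_range: tuple[float, float] = (0.2, 1.0)
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_concepts < 1:
            raise ValueError("need at least one concept")
        if not (0.0 <= self.positive_fraction <= 1.0):
            raise ValueError("positive_fraction must lie in [0, 1]")
        if self.n_relationships > self.n_concepts * (self.n_concepts - 1):
            raise ValueError(
                f"{self.n_relationships} edges infeasible for "
                f"{self.n_concepts} concepts without self-loops"
            )
        lo, hi = self.weight_magnitude_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("weight magnitudes must lie in (0, 1]")
        if self.degree_model not in ("uniform_random", "configuration"):
            raise ValueError(f"unknown degree model {self.degree_model!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int = 0) -> "GeneratorSpec":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            n_concepts=int(raw["n_concepts"]),
            n_relationships=int(raw["n_relationships"]),
            positive_fraction=float(raw.get("positive_fraction", 0.5)),
            degree_model=str(raw.get("degree_model", "uniform_random")),
            seed=seed,
            name=str(raw.get("name", Path(path).stem)),
        )


def v6_1_spec(seed: int = 0) -> GeneratorSpec:
    """The packaged spec encoding the v6.1 knowledge-base statistics."""
    from importlib import resources

    path = resources.files("fcmsim") / "fixtures" / "v6_1_stats.yaml"
    return GeneratorSpec.from_yaml(str(path), seed=seed)


def _sample_edge_codes(rng: np.random.Generator, n: int, m: int) -> list[int]:
    # codes enumerate ordered pairs (s, t != s); rejection-sample distinct codes
    space = n * (n - 1)
    chosen: dict[int, None] = {}
    while len(chosen) < m:
        for c in rng.integers(0, space, size=max(m, 1024)).tolist():
            if len(chosen) >= m:
                break
            chosen.setdefault(c)
    return list(chosen)


def _sample_configuration_codes(
    rng: np.random.Generator, n: int, m: int
) -> list[int]:
    # heavier-tailed degrees: lognormal node propensities for each endpoint
    w_out = rng.lognormal(0.0, 1.0, size=n)
    w_in = rng.lognormal(0.0, 1.0, size=n)
    p_out = w_out / w_out.sum()
    p_in = w_in / w_in.sum()
    chosen: dict[int, None] = {}
    while len(chosen) < m:
        s = rng.choice(n, size=max(m, 1024), p=p_out)
        t = rng.choice(n, size=max(m, 1024), p=p_in)
        for si, ti in zip(s.tolist(), t.tolist()):
            if len(chosen) >= m:
                break
            if si == ti:
                continue
            chosen.setdefault(si * (n - 1) + (ti if ti < si else ti - 1))
    return list(chosen)


def generate_network(spec: GeneratorSpec) -> ConceptNetwork:
    """Generate a network whose counts match ``spec`` exactly, every seed.

    Concept ids are C00001..; the first 70% are labelled gene/protein and the
    rest phenotype (the emulated statistics do not distinguish).  The edge
    set, sign assignment and magnitudes are all drawn from
    ``default_rng(spec.seed)``, so identical specs give identical networks.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_concepts, spec.n_relationships
    width = max(5, len(str(n)))
    n_gene = int(round(0.7 * n))
    concepts = [
        Concept(
            id=f"C{i + 1:0{width}d}",
            category=Category.GENE_PROTEIN if i < n_gene else Category.PHENOTYPE,
        )
        for i in range(n)
    ]
    ids = [c.id for c in concepts]

    if spec.degree_model == "configuration":
        codes = _sample_configuration_codes(rng, n, m)
    else:
        codes = _sample_edge_codes(rng, n, m)

    n_pos = int(round(spec.positive_fraction * m))
    signs = np.full(m, -1.0)
    signs[rng.permutation(m)[:n_pos]] = 1.0
    lo, hi = spec.weight_magnitude_range
    mags = rng.uniform(lo, hi, size=m)

    rels = []
    for k, code in enumerate(codes):
        s, r = divmod(code, n - 1)
        t = r if r < s else r + 1
        rels.append(Relationship(ids[s], ids[t], float(signs[k] * mags[k])))
    return ConceptNetwork(concepts, rels, name=spec.name, version="synthetic")


def embed_feature_nodes(
    network: ConceptNetwork, profile: FeatureProfile, seed: int = 0
) -> ConceptNetwork:
    """Rewire feature nodes to carry exactly their published compositions.

    For each profile feature the node is created if absent (category
    phenotype), every existing edge *into* it is replaced, and n_inputs
    distinct source concepts are drawn from the rest of the network —
    n_negative of them with negative weights, n_positive with positive.
    All other edges are untouched; re-embedding is idempotent on the
    compositions.
    """
    rng = np.random.default_rng(seed)
    net = network.copy()
    feature_ids = set(profile.feature_ids())
    pool = [c for c in net.concept_ids if c not in feature_ids]

    for feat in profile.features:
        if not feat.has_composition:
            raise ValueError(
                f"feature {feat.id!r} has no published input composition"
            )
        if feat.n_inputs > len(pool):
            raise ValueError(
                f"feature {feat.id!r} needs {feat.n_inputs} sources but the "
                f"pool holds only {len(pool)}"
            )
        if feat.id not in net:
            net.add_concept(
                Concept(id=feat.id, label=feat.label, category=Category.PHENOTYPE)
            )
        net.remove_edges_into(feat.id)
        sources = rng.choice(len(pool), size=feat.n_inputs, replace=False)
        mags = rng.uniform(0.2, 1.0, size=feat.n_inputs)
        for k, (src_i, mag) in enumerate(zip(sources.tolist(), mags.tolist())):
            sign = -1.0 if k < feat.n_negative_inputs else 1.0
            net.add_relationship(Relationship(pool[src_i], feat.id, sign * mag))
    return net


def designed_outcome_network(
    profile: FeatureProfile,
    directions: dict[str, str],
    seed: int = 0,
) -> tuple[ConceptNetwork, ClampSpec]:
    """Acyclic network + clamps with analytically known feature signs.

    A single driver concept is clamped ON; each feature hangs off its own
    relay (driver -> relay -> feature) with the relay->feature weight signed
    by the assigned direction, so forward evaluation gives the feature
    activation tanh(+/- w2 * tanh(w1)) whose sign equals the assignment.
    Every node has at most one input with |weight| < 1, so the iteration is
    a max-norm contraction and convergence is guaranteed.  Flipping one
    assignment flips exactly that feature's edge sign.
    """
    missing = [f.id for f in profile.features if f.id not in directions]
    if missing:
        raise ValueError(f"directions missing for features: {missing}")
    rng = np.random.default_rng(seed)
    driver = "DRIVER"
    concepts = [Concept(id=driver, category=Category.ENVIRONMENT)]
    rels = []
    for feat in profile.features:
        d = directions[feat.id]
        if d not in ("up", "down"):
            raise ValueError(f"bad direction {d!r} for {feat.id!r}")
        relay = f"{feat.id}__relay"
        w1 = float(rng.uniform(0.5, 0.9))
        w2 = float(rng.uniform(0.5, 0.9))
        concepts.append(Concept(id=relay, category=Category.GENE_PROTEIN))
        concepts.append(
            Concept(id=feat.id, label=feat.label, category=Category.PHENOTYPE)
        )
        rels.append(Relationship(driver, relay, w1))
        rels.append(Relationship(relay, feat.id, w2 if d == "up" else -w2))
    net = ConceptNetwork(concepts, rels, name=f"designed_{profile.name}")
    return net, ClampSpec.from_parts(locked_on=[driver])
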