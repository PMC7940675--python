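"""Shared builders for randomized network fixtures."""

import numpy as np
import pytest

from fcmsim import ClampSpec, Concept, ConceptNetwork, Relationship


def make_random_network(rng: np.random.Generator, n_min: int = 3, n_max: int = 12,
                        edge_prob: float = 0.35) -> ConceptNetwork:
    """A small random signed network (weights uniform in [-1,1] minus 0)."""
    n = int(rng.integers(n_min, n_max + 1))
    ids = [f"N{i}" for i in range(n)]
    net = ConceptNetwork([Concept(i) for i in ids], name="random")
    for s in ids:
        for t in ids:
            if s != t and rng.random() < edge_prob:
                w = float(rng.uniform(-1.0, 1.0))
                if w == 0.0:
                    w = 0.5
                net.add_relationship(Relationship(s, t, w))
    return net


def make_random_clamps(rng: np.random.Generator, net: ConceptNetwork,
                       max_frac: float = 0.4) -> ClampSpec:
    ids = list(net.concept_ids)
    k = int(rng.integers(0, max(1, int(len(ids) * max_frac)) + 1))
    chosen = rng.choice(len(ids), size=k, replace=False) if k else []
    entries = {}
    for i in chosen:
        entries[ids[int(i)]] = float(rng.choice([-1.0, 1.0, float(rng.uniform(-1, 1))]))
    return ClampSpec(entries)


def make_random_dag(rng: np.random.Generator, n_min: int = 3, n_max: int = 10) -> ConceptNetwork:
    """A random DAG whose edges only point from lower to higher index."""
    n = int(rng.integers(n_min, n_max + 1))
    ids = [f"D{i}" for i in range(n)]
    net = ConceptNetwork([Concept(i) for i in ids], name="dag")
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.4:
                w = float(rng.uniform(-1.0, 1.0)) or 0.3
                net.add_relationship(Relationship(ids[i], ids[j], w))
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
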