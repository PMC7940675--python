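"""Signed weighted concept networks: data model, validation, I/O and summaries.

A concept network is a directed graph whose nodes ("concepts") are
genes/proteins, phenotypic features or environmental inputs, and whose edges
("relationships") carry a signed weight in [-1, +1] excluding zero.  A row
``(source, target, w)`` means *source influences target* with strength ``w``;
positive weights promote the target, negative weights inhibit it.  Concept
activations live in [-1, +1] around a zero baseline, so the network doubles as
the substrate of a fuzzy cognitive map: the simulator iterates it under
clamped inputs to a steady state.

Networks are read and written as UTF-8 TSV edge lists (header
``source<TAB>target<TAB>weight``) with an optional JSON sidecar carrying
concept labels and categories, or as GraphML for graph viewers.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional

import networkx as nx

__all__ = [
    "Category",
    "Concept",
    "Relationship",
    "ConceptNetwork",
    "NetworkSummary",
    "NetworkValidationError",
    "read_network",
    "write_network",
    "network_summary",
    "pretest_probabilities",
]


class NetworkValidationError(ValueError):
    """An input violates a structural invariant of the network model."""


class Category(str, Enum):
    """What kind of entity a concept stands for."""

    GENE_PROTEIN = "gene_protein"
    PHENOTYPE = "phenotype"
    ENVIRONMENT = "environment"


@dataclass(frozen=True)
class Concept:
    """A node: a gene/protein, phenotypic feature or environmental input.

    ``baseline`` is the resting activation and is always 0 — activations are
    reported relative to an arbitrary zero baseline, with +1 maximum
    expression/presence and -1 minimum.
    """

    id: str
    label: str = ""
    category: Category = Category.PHENOTYPE
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("concept id must be a non-empty string")
        if self.baseline != 0.0:
            raise NetworkValidationError(
                f"concept {self.id!r}: baseline must be 0 (got {self.baseline})"
            )


@dataclass(frozen=True)
class Relationship:
    """A directed signed influence of ``source`` on ``target``.

    Weights are signed reals in [-1, +1]; zero is forbidden (only non-zero
    relationships exist), so a sign-only network uses weights of exactly +/-1.
    """

    source: str
    target: str
    weight: float

    def __post_init__(self) -> None:
        w = self.weight
        if not math.isfinite(w) or w == 0.0 or abs(w) > 1.0:
            raise NetworkValidationError(
                f"relationship {self.source}->{self.target}: weight must be a "
                f"non-zero real in [-1, +1] (got {w!r})"
            )


class ConceptNetwork:
    """A validated collection of concepts plus signed relationships.

    Invariants enforced on construction and mutation:

    * concept ids are unique;
    * every relationship endpoint resolves to a concept;
    * no duplicate ``(source, target)`` pairs (parallel edges are an error,
      never a silent merge);
    * weights are non-zero and within [-1, +1].

    Self-loops are allowed (no exclusion rule applies to them anywhere, and
    they count toward the sign composition like any other edge).
    """

    def __init__(
        self,
        concepts: Iterable[Concept] = (),
        relationships: Iterable[Relationship] = (),
        name: str = "",
        version: str = "",
    ) -> None:
        self.name = name
        self.version = version
        self._concepts: dict[str, Concept] = {}
        self._edges: dict[tuple[str, str], Relationship] = {}
        for c in concepts:
            self.add_concept(c)
        for r in relationships:
            self.add_relationship(r)

    # -- mutation ----------------------------------------------------------

    def add_concept(self, concept: Concept) -> None:
        if concept.id in self._concepts:
            raise NetworkValidationError(f"duplicate concept id {concept.id!r}")
        self._concepts[concept.id] = concept

    def add_relationship(self, rel: Relationship) -> None:
        key = (rel.source, rel.target)
        if key in self._edges:
            raise NetworkValidationError(
                f"duplicate relationship {rel.source}->{rel.target}"
            )
        for endpoint in key:
            if endpoint not in self._concepts:
                raise NetworkValidationError(
                    f"relationship {rel.source}->{rel.target}: unknown concept "
                    f"{endpoint!r}"
                )
        self._edges[key] = rel

    def remove_edges_into(self, target: str) -> int:
        """Drop every relationship whose target is ``target``; return count."""
        keys = [k for k in self._edges if k[1] == target]
        for k in keys:
            del self._edges[k]
        return len(keys)

    # -- access ------------------------------------------------------------

    @property
    def concepts(self) -> tuple[Concept, ...]:
        return tuple(self._concepts.values())

    @property
    def concept_ids(self) -> tuple[str, ...]:
        return tuple(self._concepts)

    @property
    def relationships(self) -> tuple[Relationship, ...]:
        return tuple(self._edges.values())

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._concepts

    def __len__(self) -> int:
        return len(self._concepts)

    def concept(self, concept_id: str) -> Concept:
        return self._concepts[concept_id]

    def in_edges(self, target: str) -> list[Relationship]:
        return [r for (s, t), r in self._edges.items() if t == target]

    def in_degree(self, target: str) -> int:
        return sum(1 for (s, t) in self._edges if t == target)

    def out_degree(self, source: str) -> int:
        return sum(1 for (s, t) in self._edges if s == source)

    def copy(self) -> "ConceptNetwork":
        return ConceptNetwork(
            self.concepts, self.relationships, name=self.name, version=self.version
        )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(name=self.name, version=self.version)
        for c in self.concepts:
            g.add_node(c.id, label=c.label, category=c.category.value)
        for r in self.relationships:
            g.add_edge(r.source, r.target, weight=r.weight)
        return g

    def __iter__(self) -> Iterator[Concept]:
        return iter(self.concepts)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ConceptNetwork(name={self.name!r}, n_concepts={len(self)}, "
            f"n_relationships={len(self.relationships)})"
        )


@dataclass(frozen=True)
class NetworkSummary:
    """Counts and sign-composition statistics of a network.

    ``positive_fraction`` is the pretest probability of a positive prediction
    (the chance, under the network's sign bias, that an arbitrary prediction
    is positive); ``negative_fraction`` is its complement.  For an empty
    network the fraction and degree fields are ``None`` and ``defined`` is
    False rather than NaN.
    """

    n_concepts: int
    n_relationships: int
    n_positive: int
    n_negative: int
    positive_fraction: Optional[float]
    negative_fraction: Optional[float]
    mean_in_degree: Optional[float]
    mean_out_degree: Optional[float]

    @property
    def defined(self) -> bool:
        return self.positive_fraction is not None

    def rounded(self, decimals: int = 3) -> dict[str, object]:
        """Printed-precision rendering (3 decimals by default)."""
        out: dict[str, object] = {
            "n_concepts": self.n_concepts,
            "n_relationships": self.n_relationships,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }
        for k in (
            "positive_fraction",
            "negative_fraction",
            "mean_in_degree",
            "mean_out_degree",
        ):
            v = getattr(self, k)
            out[k] = None if v is None else round(v, decimals)
        return out


def network_summary(network: ConceptNetwork) -> NetworkSummary:
    """Exact counts plus sign fractions and mean degrees.

    Every relationship has one source and one target, so the mean in-degree
    and mean out-degree are both ``n_relationships / n_concepts``.
    """
    rels = network.relationships
    n_c = len(network)
    n_r = len(rels)
    n_pos = sum(1 for r in rels if r.weight > 0)
    n_neg = n_r - n_pos
    if n_r == 0 or n_c == 0:
        frac_pos = frac_neg = None
        mean_deg = None if n_c == 0 else n_r / n_c
    else:
        frac_pos = n_pos / n_r
        frac_neg = n_neg / n_r
        mean_deg = n_r / n_c
    return NetworkSummary(
        n_concepts=n_c,
        n_relationships=n_r,
        n_positive=n_pos,
        n_negative=n_neg,
        positive_fraction=frac_pos,
        negative_fraction=frac_neg,
        mean_in_degree=mean_deg,
        mean_out_degree=mean_deg,
    )


def pretest_probabilities(network: ConceptNetwork) -> tuple[float, float]:
    """Chance probabilities (p_pos, p_neg) of a positive/negative prediction.

    Derived from the edge-sign composition: ``p_pos = n_positive /
    n_relationships`` and ``p_neg = 1 - p_pos``.  These feed the
    bias-compensated binomial test as the per-prediction success
    probabilities under the null.
    """
    summary = network_summary(network)
    if summary.n_relationships == 0:
        raise NetworkValidationError(
            "pretest probabilities undefined for a network with no relationships"
        )
    p_pos = summary.n_positive / summary.n_relationships
    return p_pos, 1.0 - p_pos


# -- I/O -------------------------------------------------------------------

_TSV_HEADER = ("source", "target", "weight")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".concepts.json")


def _read_sidecar(path: Path) -> dict[str, dict[str, str]]:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise NetworkValidationError(f"{path}: sidecar must be a JSON object")
    return raw


def read_network(
    path: str | Path,
    format: str = "tsv",
    sidecar: str | Path | None = None,
) -> ConceptNetwork:
    """Read a network from a TSV edge list or a GraphML file.

    For TSV, a JSON sidecar ``{id: {label, category}}`` is honoured when
    present (``<stem>.concepts.json`` next to the edge list, or an explicit
    ``sidecar`` path).  Concepts that appear only in edges and not in the
    sidecar are created with category ``phenotype`` and a warning.
    """
    path = Path(path)
    if format == "graphml":
        return _read_graphml(path)
    if format != "tsv":
        raise ValueError(f"unknown network format {format!r}")

    meta: dict[str, dict[str, str]] = {}
    sidecar_path = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if sidecar_path.exists():
        meta = _read_sidecar(sidecar_path)

    net = ConceptNetwork(name=path.stem)
    for cid, info in meta.items():
        net.add_concept(
            Concept(
                id=cid,
                label=str(info.get("label", "")),
                category=Category(info.get("category", "phenotype")),
            )
        )

    edge_only: list[str] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header and tuple(header.rstrip("\n").split("\t")) != _TSV_HEADER:
            raise NetworkValidationError(
                f"{path}: line 1: expected header "
                f"'source\\ttarget\\tweight', got {header.rstrip()!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise NetworkValidationError(
                    f"{path}: line {lineno}: expected 3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            source, target, raw_w = parts
            try:
                weight = float(raw_w)
            except ValueError:
                raise NetworkValidationError(
                    f"{path}: line {lineno}: weight {raw_w!r} is not a number"
                ) from None
            for cid in (source, target):
                if cid not in net:
                    net.add_concept(Concept(id=cid, category=Category.PHENOTYPE))
                    if meta:
                        edge_only.append(cid)
            try:
                net.add_relationship(Relationship(source, target, weight))
            except NetworkValidationError as exc:
                raise NetworkValidationError(f"{path}: line {lineno}: {exc}") from None

    if edge_only:
        warnings.warn(
            f"{path}: {len(edge_only)} concept(s) appear only in edges and "
            f"were created with category 'phenotype': {sorted(edge_only)[:5]}...",
            stacklevel=2,
        )
    return net


def _read_graphml(path: Path) -> ConceptNetwork:
    g = nx.read_graphml(path)
    net = ConceptNetwork(name=g.graph.get("name", path.stem))
    for node, data in g.nodes(data=True):
        net.add_concept(
            Concept(
                id=str(node),
                label=str(data.get("label", "")),
                category=Category(data.get("category", "phenotype")),
            )
        )
    for s, t, data in g.edges(data=True):
        if "weight" not in data:
            raise NetworkValidationError(f"{path}: edge {s}->{t} has no weight")
        net.add_relationship(Relationship(str(s), str(t), float(data["weight"])))
    return net


def write_network(
    network: ConceptNetwork,
    path: str | Path,
    format: str = "tsv",
    sidecar: str | Path | None = None,
) -> None:
    """Write a network; ``read_network(write_network(x))`` round-trips exactly.

    Weights are serialised with :func:`repr` so every IEEE double survives the
    text round trip bit-for-bit.  TSV output always writes the JSON sidecar so
    categories and labels round-trip too.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(network.to_networkx(), path)
        return
    if format != "tsv":
        raise ValueError(f"unknown network format {format!r}")

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for r in network.relationships:
            fh.write(f"{r.source}\t{r.target}\t{r.weight!r}\n")

    sidecar_path = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    meta = {
        c.id: {"label": c.label, "category": c.category.value}
        for c in network.concepts
    }
    with open(sidecar_path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
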