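"""Experimental protocols ("cocktails") and literature feature profiles.

A protocol is the in-silico analogue of a wet-lab differentiation recipe: a
named set of clamps (reprogramming factors, media components, bioreactor
environment locked ON/OFF, an AGE input fixed on a [-1, +1] scale) plus the
feature panels against which the resulting steady state is scored.  A
feature profile is a literature-derived panel of concepts with expected
directions (and, where published, the signed composition of each feature's
inputs in the knowledge base).

Packaged fixtures ship under ``fcmsim/fixtures``: the wild-type
pluripotent-to-whole-brain-organoid cocktail, its Alzheimer's variant
(APOE4 locked ON, amyloid-beta clearance locked OFF), and one profile per
validation panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Sequence

import yaml

from .simulator import ClampSpec, ReplicateSummary

__all__ = [
    "Feature",
    "FeatureProfile",
    "PredictionOutcome",
    "Protocol",
    "age_to_input",
    "load_protocol",
    "load_profile",
    "packaged_profile",
    "packaged_protocol",
    "list_packaged_profiles",
    "evaluate_profile",
    "AGE_CONCEPT",
]

AGE_CONCEPT = "AGE"

Direction = Literal["up", "down"]


def age_to_input(age_years: float) -> float:
    """Map an age in years onto the [-1, +1] AGE input scale.

    Anchors: -1 at birth, 0 at 50 years, +1 at >= 100 years; linear between
    them, i.e. ``(age - 50) / 50`` clamped above at +1.
    """
    if age_years < 0:
        raise ValueError(f"age must be >= 0 (got {age_years})")
    return min((age_years - 50.0) / 50.0, 1.0)


@dataclass(frozen=True)
class Feature:
    """One panel entry: a concept with its literature-expected direction.

    Where the knowledge base's composition for the feature is published,
    ``n_inputs = n_negative_inputs + n_positive_inputs`` records how many
    signed relationships feed it (negative inputs inhibit the feature,
    positive inputs promote it); otherwise the counts are None.
    """

    id: str
    expected: Direction = "up"
    label: str = ""
    n_inputs: Optional[int] = None
    n_negative_inputs: Optional[int] = None
    n_positive_inputs: Optional[int] = None

    def __post_init__(self) -> None:
        if self.expected not in ("up", "down"):
            raise ValueError(f"feature {self.id!r}: bad direction {self.expected!r}")
        counts = (self.n_inputs, self.n_negative_inputs, self.n_positive_inputs)
        if any(c is not None for c in counts):
            if any(c is None for c in counts):
                raise ValueError(
                    f"feature {self.id!r}: partial input composition"
                )
            if self.n_negative_inputs + self.n_positive_inputs != self.n_inputs:
                raise ValueError(
                    f"feature {self.id!r}: composition "
                    f"{self.n_negative_inputs}+{self.n_positive_inputs} != "
                    f"{self.n_inputs}"
                )

    @property
    def has_composition(self) -> bool:
        return self.n_inputs is not None


@dataclass(frozen=True)
class FeatureProfile:
    name: str
    features: tuple[Feature, ...]
    description: str = ""

    def __len__(self) -> int:
        return len(self.features)

    def feature_ids(self) -> tuple[str, ...]:
        return tuple(f.id for f in self.features)

    def __add__(self, other: "FeatureProfile") -> "FeatureProfile":
        return FeatureProfile(
            name=f"{self.name}+{other.name}",
            features=self.features + other.features,
        )


@dataclass(frozen=True)
class PredictionOutcome:
    """Agreement call for one feature against the simulated steady state."""

    feature_id: str
    predicted_direction: Literal["up", "down", "null"]
    expected_direction: Direction
    agree: bool
    mean_activation: float


@dataclass(frozen=True)
class Protocol:
    """A named cocktail: clamps plus the panels it is scored against."""

    name: str
    clamps: ClampSpec
    age_years: Optional[float] = None
    profiles: tuple[str, ...] = ()
    metadata: dict = field(default_factory=dict)


# -- packaged fixtures -----------------------------------------------------

_FIXTURES = resources.files("fcmsim") / "fixtures"


def _fixture_path(kind: str, name: str) -> Path:
    p = Path(str(_FIXTURES / kind / f"{name}.yaml"))
    if not p.exists():
        raise FileNotFoundError(f"no packaged {kind[:-1]} named {name!r}")
    return p


def list_packaged_profiles() -> list[str]:
    return sorted(
        p.stem for p in Path(str(_FIXTURES / "profiles")).glob("*.yaml")
    )


def load_profile(path: str | Path) -> FeatureProfile:
    """Load a feature profile from YAML (supports ``includes`` of packaged
    panels, used by the combined whole-organoid panel)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not raw:
        raise ValueError(f"{path}: empty profile file")
    features: list[Feature] = []
    for inc in raw.get("includes", []):
        features.extend(packaged_profile(inc).features)
    for entry in raw.get("features", []):
        features.append(
            Feature(
                id=str(entry["id"]),
                expected=entry.get("expected", "up"),
                label=str(entry.get("label", "")),
                n_inputs=entry.get("n_inputs"),
                n_negative_inputs=entry.get("n_negative_inputs"),
                n_positive_inputs=entry.get("n_positive_inputs"),
            )
        )
    if not features:
        raise ValueError(f"{path}: profile defines no features")
    return FeatureProfile(
        name=str(raw.get("name", path.stem)),
        features=tuple(features),
        description=str(raw.get("description", "")),
    )


def packaged_profile(name: str) -> FeatureProfile:
    return load_profile(_fixture_path("profiles", name))


def load_protocol(path: str | Path) -> Protocol:
    """Load a protocol file (YAML); ``extends`` merges a base protocol.

    The file lists ``locked_on`` / ``locked_off`` concept ids and optional
    ``fixed`` values; ``age_years`` adds a fixed clamp for the AGE concept at
    ``age_to_input(age_years)``.  A concept appearing with two different
    clamp values is an error.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not raw:
        raise ValueError(f"{path}: empty protocol file")

    base: Optional[Protocol] = None
    if "extends" in raw:
        parent = raw["extends"]
        parent_path = (
            Path(parent)
            if Path(parent).suffix
            else _fixture_path("protocols", parent)
        )
        base = load_protocol(parent_path)

    locked_on = [str(c) for c in raw.get("locked_on", [])]
    locked_off = [str(c) for c in raw.get("locked_off", [])]
    fixed = {str(k): float(v) for k, v in (raw.get("fixed") or {}).items()}
    age_years = raw.get("age_years")
    if age_years is None and base is not None:
        age_years = base.age_years
    if age_years is not None:
        fixed.setdefault(AGE_CONCEPT, age_to_input(float(age_years)))

    own = ClampSpec.from_parts(locked_on, locked_off, fixed)
    clamps = base.clamps.merged_with(own) if base is not None else own
    profiles = tuple(raw.get("profiles", base.profiles if base else ()))
    metadata = dict(base.metadata) if base else {}
    metadata.update(raw.get("metadata", {}))
    return Protocol(
        name=str(raw.get("name", path.stem)),
        clamps=clamps,
        age_years=None if age_years is None else float(age_years),
        profiles=profiles,
        metadata=metadata,
    )


def packaged_protocol(name: str) -> Protocol:
    return load_protocol(_fixture_path("protocols", name))


# -- scoring ---------------------------------------------------------------

def evaluate_profile(
    summary: ReplicateSummary,
    profile: FeatureProfile,
    threshold: float = 0.0,
) -> list[PredictionOutcome]:
    """Score a simulated steady state against a feature panel.

    A feature is called up if its mean activation exceeds ``threshold``,
    down if below ``-threshold``, and null otherwise (strict inequalities:
    an exact-zero mean under the default threshold is null and never an
    agreement).  An agreement is a predicted direction equal to the
    literature-expected one.
    """
    outcomes: list[PredictionOutcome] = []
    for feat in profile.features:
        if feat.id not in summary.concept_ids:
            raise KeyError(
                f"profile {profile.name!r}: feature {feat.id!r} not present "
                f"in the simulation summary"
            )
        mean = summary.mean_activation(feat.id)
        if mean > threshold:
            predicted = "up"
        elif mean < -threshold:
            predicted = "down"
        else:
            predicted = "null"
        outcomes.append(
            PredictionOutcome(
                feature_id=feat.id,
                predicted_direction=predicted,
                expected_direction=feat.expected,
                agree=predicted == feat.expected,
                mean_activation=mean,
            )
        )
    return outcomes
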