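"""Iterate a clamped concept network to a system-wide steady state.

The simulator treats the network as a fuzzy cognitive map: activations
``x in [-1, +1]^n`` evolve synchronously under

    x_i(t+1) = squash( sum_j w_ij * x_j(t) )

where ``w_ij`` is the weight of the relationship j -> i and the squashing
function is ``tanh`` by default (a bipolar sigmoid is available).  Clamped
concepts — the in-silico "cocktail" of locked-ON (+1), locked-OFF (-1) or
fixed-value inputs — are reset to their clamp value after every update, so an
intervention never decays.

Convergence is declared when the max-norm change stays below a tolerance for
a run of consecutive steps; iteration then *continues* to the horizon and any
later departure from the recorded steady state is flagged as overtraining
(a limit cycle or divergence masquerading as convergence).  Replicates differ
only through the random initialisation of unclamped concepts, each drawn from
a deterministic per-replicate substream of the seed, so every run is exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .network import ConceptNetwork, NetworkValidationError
from .stats import replicate_ci

__all__ = [
    "ClampSpec",
    "SimulationConfig",
    "StateVector",
    "SimulationResult",
    "ReplicateSummary",
    "SimulationError",
    "initialize_state",
    "step",
    "simulate",
    "run_replicates",
]

LOCKED_ON = 1.0
LOCKED_OFF = -1.0


class SimulationError(RuntimeError):
    """Numerical failure (non-finite activation) during iteration."""


@dataclass(frozen=True)
class ClampSpec:
    """Concepts held fixed throughout a simulation.

    ``entries`` maps concept id -> clamp value: +1 locked ON, -1 locked OFF,
    or any fixed value in [-1, +1] (e.g. the AGE input).  Conflicting clamp
    requests for one id are an error at construction, never a silent
    precedence.
    """

    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        for cid, v in self.entries.items():
            if not (-1.0 <= v <= 1.0):
                raise NetworkValidationError(
                    f"clamp for {cid!r} must lie in [-1, +1] (got {v})"
                )
        object.__setattr__(self, "entries", dict(self.entries))

    @classmethod
    def from_parts(
        cls,
        locked_on: Sequence[str] = (),
        locked_off: Sequence[str] = (),
        fixed: Mapping[str, float] | None = None,
    ) -> "ClampSpec":
        entries: dict[str, float] = {}
        for cid, value in (
            *((c, LOCKED_ON) for c in locked_on),
            *((c, LOCKED_OFF) for c in locked_off),
            *((fixed or {}).items()),
        ):
            if cid in entries and entries[cid] != value:
                raise NetworkValidationError(
                    f"conflicting clamp entries for {cid!r}: "
                    f"{entries[cid]} vs {value}"
                )
            entries[cid] = float(value)
        return cls(entries)

    def validate_against(self, network: ConceptNetwork) -> None:
        unknown = sorted(c for c in self.entries if c not in network)
        if unknown:
            raise NetworkValidationError(
                f"clamped concept(s) not in network: {unknown}"
            )

    def merged_with(self, other: "ClampSpec") -> "ClampSpec":
        return ClampSpec.from_parts(fixed={**self.entries, **other.entries})

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class SimulationConfig:
    """Tunable parameters of the iteration.

    tolerance
        convergence threshold on the max per-concept change per step.
    max_iterations
        the overtraining horizon: iteration always runs this far so
        post-convergence drift can be detected (default 1000).
    consecutive_stable_steps
        how many successive sub-tolerance steps declare a steady state.
    squash
        ``tanh`` (default) or ``bipolar_sigmoid`` (2/(1+e^-x) - 1).
    init_mode
        ``zeros`` for deterministic runs, or ``uniform_random`` drawing
        unclamped concepts from [-init_epsilon, +init_epsilon].
    replicates / seed
        experiments are run in seeded replicates (default 3, "triplicate");
        replicate r uses the substream SeedSequence([seed, r]).
    """

    tolerance: float = 1e-6
    max_iterations: int = 1000
    consecutive_stable_steps: int = 3
    squash: Literal["tanh", "bipolar_sigmoid"] = "tanh"
    init_mode: Literal["zeros", "uniform_random"] = "zeros"
    init_epsilon: float = 0.1
    replicates: int = 3
    seed: int = 0
    record_trajectory: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.tolerance < 1.0):
            raise ValueError("tolerance must lie in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.consecutive_stable_steps < 1:
            raise ValueError("consecutive_stable_steps must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.squash not in ("tanh", "bipolar_sigmoid"):
            raise ValueError(f"unknown squash {self.squash!r}")
        if self.init_mode not in ("zeros", "uniform_random"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")


def _squash_fn(name: str):
    if name == "tanh":
        return np.tanh
    return lambda x: 2.0 / (1.0 + np.exp(-x)) - 1.0  # bipolar sigmoid = tanh(x/2)


@dataclass(frozen=True)
class StateVector:
    """Activations of every concept at one iteration, each in [-1, +1]."""

    concept_ids: tuple[str, ...]
    values: np.ndarray
    iteration: int = 0

    def __getitem__(self, concept_id: str) -> float:
        return float(self.values[self.concept_ids.index(concept_id)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.concept_ids, map(float, self.values)))


@dataclass(frozen=True)
class SimulationResult:
    """One replicate's outcome: steady state plus convergence diagnostics.

    ``iterations_to_converge`` is the iteration at which the stability run
    completed; ``overtraining_detected`` means the state later departed from
    the recorded steady state by at least the tolerance.
    """

    steady_state: StateVector
    converged: bool
    iterations_to_converge: Optional[int]
    overtraining_detected: bool
    final_state: StateVector
    trajectory: Optional[tuple[StateVector, ...]] = None


def _weight_matrix(
    network: ConceptNetwork, order: tuple[str, ...]
) -> sp.csr_matrix:
    """W[i, j] = weight of the relationship order[j] -> order[i]."""
    index = {cid: k for k, cid in enumerate(order)}
    rels = network.relationships
    rows = np.fromiter((index[r.target] for r in rels), dtype=np.int64, count=len(rels))
    cols = np.fromiter((index[r.source] for r in rels), dtype=np.int64, count=len(rels))
    data = np.fromiter((r.weight for r in rels), dtype=np.float64, count=len(rels))
    n = len(order)
    return sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()


def _clamp_arrays(
    clamps: ClampSpec, order: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    index = {cid: k for k, cid in enumerate(order)}
    idx = np.fromiter(
        (index[c] for c in clamps.entries), dtype=np.int64, count=len(clamps)
    )
    vals = np.fromiter(clamps.entries.values(), dtype=np.float64, count=len(clamps))
    return idx, vals


def initialize_state(
    network: ConceptNetwork,
    clamps: ClampSpec,
    config: SimulationConfig,
    replicate_index: int = 0,
) -> StateVector:
    """Initial activations: clamps applied, unclamped concepts at baseline.

    In ``uniform_random`` mode unclamped concepts are drawn uniformly from
    [-init_epsilon, +init_epsilon] using the deterministic substream
    ``SeedSequence([seed, replicate_index])``, the sole source of replicate
    variability.
    """
    clamps.validate_against(network)
    order = network.concept_ids
    x = np.zeros(len(order))
    if config.init_mode == "uniform_random":
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, replicate_index])
        )
        x = rng.uniform(-config.init_epsilon, config.init_epsilon, size=len(order))
    idx, vals = _clamp_arrays(clamps, order)
    if len(idx):
        x[idx] = vals
    return StateVector(concept_ids=order, values=x, iteration=0)


def step(
    network: ConceptNetwork,
    state: StateVector,
    clamps: ClampSpec,
    config: SimulationConfig = SimulationConfig(),
) -> StateVector:
    """One synchronous update x' = squash(W x), then re-apply clamps.

    A concept with no inputs relaxes to squash(0) = 0; clamped concepts are
    hard-reset to their clamp values after the squash.
    """
    W = _weight_matrix(network, state.concept_ids)
    idx, vals = _clamp_arrays(clamps, state.concept_ids)
    squash = _squash_fn(config.squash)
    x = np.asarray(squash(W @ state.values))
    if len(idx):
        x[idx] = vals
    return StateVector(
        concept_ids=state.concept_ids, values=x, iteration=state.iteration + 1
    )


def simulate(
    network: ConceptNetwork,
    clamps: ClampSpec,
    config: SimulationConfig = SimulationConfig(),
    replicate_index: int = 0,
) -> SimulationResult:
    """Iterate to a steady state, then keep going to probe for overtraining.

    The state is stepped synchronously until the max per-concept change stays
    below ``config.tolerance`` for ``config.consecutive_stable_steps``
    consecutive steps; the first such iteration is recorded as the steady
    state.  Iteration then continues to ``config.max_iterations`` and any
    later excursion of at least the tolerance away from the recorded steady
    state sets ``overtraining_detected`` (limit cycle or divergence).  If
    stability is never reached, ``converged`` is False and the final state is
    reported as the (non-steady) ``steady_state`` surrogate.
    """
    clamps.validate_against(network)
    order = network.concept_ids
    W = _weight_matrix(network, order)
    clamp_idx, clamp_vals = _clamp_arrays(clamps, order)
    squash = _squash_fn(config.squash)

    state0 = initialize_state(network, clamps, config, replicate_index)
    x = state0.values.copy()
    trajectory: list[StateVector] = [state0] if config.record_trajectory else []

    converged = False
    iterations_to_converge: Optional[int] = None
    overtraining = False
    steady: Optional[np.ndarray] = None
    stable_run = 0

    for t in range(1, config.max_iterations + 1):
        x_new = np.asarray(squash(W @ x))
        if len(clamp_idx):
            x_new[clamp_idx] = clamp_vals
        if not np.all(np.isfinite(x_new)):
            raise SimulationError(f"non-finite activation at iteration {t}")
        delta = float(np.max(np.abs(x_new - x))) if len(x) else 0.0
        x = x_new
        if config.record_trajectory:
            trajectory.append(StateVector(order, x.copy(), iteration=t))

        if not converged:
            stable_run = stable_run + 1 if delta < config.tolerance else 0
            if stable_run >= config.consecutive_stable_steps:
                converged = True
                iterations_to_converge = t
                steady = x.copy()
        elif steady is not None:
            if len(x) and float(np.max(np.abs(x - steady))) >= config.tolerance:
                overtraining = True

    final = StateVector(order, x, iteration=config.max_iterations)
    steady_state = (
        StateVector(order, steady, iteration=iterations_to_converge)
        if steady is not None
        else final
    )
    return SimulationResult(
        steady_state=steady_state,
        converged=converged,
        iterations_to_converge=iterations_to_converge,
        overtraining_detected=overtraining,
        final_state=final,
        trajectory=tuple(trajectory) if config.record_trajectory else None,
    )


@dataclass(frozen=True)
class ReplicateSummary:
    """Per-concept mean steady-state activation with 95% t-based CIs.

    Aggregates exactly ``n_replicates`` seeded runs; per-replicate steady
    states are retained for between-condition comparisons.
    """

    concept_ids: tuple[str, ...]
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_replicates: int
    results: tuple[SimulationResult, ...]
    seeds: tuple[int, ...]
    ci_level: float = 0.95

    def mean_activation(self, concept_id: str) -> float:
        return float(self.mean[self.concept_ids.index(concept_id)])

    def replicate_values(self, concept_id: str) -> np.ndarray:
        """Steady-state activations of one concept across replicates."""
        k = self.concept_ids.index(concept_id)
        return np.array([r.steady_state.values[k] for r in self.results])

    def to_frame(self):
        import pandas as pd

        data = {
            "concept_id": list(self.concept_ids),
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_replicates": self.n_replicates,
        }
        for i in range(self.n_replicates):
            data[f"rep{i}"] = self.results[i].steady_state.values
        return pd.DataFrame(data)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path: str | Path) -> "ReplicateSummary":
        """Rehydrate the per-concept values written by :meth:`write_csv`.

        Per-replicate simulation diagnostics are not stored in the CSV, so
        ``results`` is reconstructed as bare steady-state holders.
        """
        import pandas as pd

        df = pd.read_csv(path, float_precision="round_trip")
        order = tuple(df["concept_id"].astype(str))
        n_rep = int(df["n_replicates"].iloc[0])
        results = []
        for i in range(n_rep):
            sv = StateVector(order, df[f"rep{i}"].to_numpy(dtype=float))
            results.append(
                SimulationResult(
                    steady_state=sv,
                    converged=True,
                    iterations_to_converge=None,
                    overtraining_detected=False,
                    final_state=sv,
                )
            )
        return cls(
            concept_ids=order,
            mean=df["mean"].to_numpy(dtype=float),
            ci_low=df["ci_low"].to_numpy(dtype=float),
            ci_high=df["ci_high"].to_numpy(dtype=float),
            n_replicates=n_rep,
            results=tuple(results),
            seeds=(),
        )


def run_replicates(
    network: ConceptNetwork,
    clamps: ClampSpec,
    config: SimulationConfig = SimulationConfig(),
) -> ReplicateSummary:
    """Run ``config.replicates`` seeded simulations and aggregate them.

    Replicate r uses the deterministic substream ``SeedSequence([seed, r])``;
    the whole summary is bit-reproducible given (network, clamps, config).
    CIs are two-sided t-based at 95% with ``replicates - 1`` degrees of
    freedom (zero-width when the replicates are identical, e.g. zeros init).
    """
    results = []
    for r in range(config.replicates):
        try:
            results.append(simulate(network, clamps, config, replicate_index=r))
        except SimulationError as exc:
            raise SimulationError(f"replicate {r}: {exc}") from exc

    order = network.concept_ids
    values = np.array([res.steady_state.values for res in results])  # (reps, n)
    mean = np.empty(len(order))
    low = np.empty(len(order))
    high = np.empty(len(order))
    for k in range(len(order)):
        mean[k], low[k], high[k] = replicate_ci(values[:, k])
    return ReplicateSummary(
        concept_ids=order,
        mean=mean,
        ci_low=low,
        ci_high=high,
        n_replicates=config.replicates,
        results=tuple(results),
        seeds=tuple(range(config.replicates)),
    )
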