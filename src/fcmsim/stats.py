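"""Statistical layer: bias-compensated binomial panel test, exact
Mann-Whitney U, replicate confidence intervals and condition comparisons.

The panel test asks: given a literature-derived panel of N directional
predictions, what is the probability that at least the observed number of
agreements arose by chance, when the network's sign composition biases a
chance prediction toward "up" with probability p_pos (and "down" with
p_neg = 1 - p_pos)?  Each prediction therefore carries its own chance
probability and the null distribution of the agreement count is
Poisson-binomial; for a homogeneous all-up panel that all agrees it reduces
to the closed form p_pos**N.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats as sps

if TYPE_CHECKING:  # pragma: no cover
    from .protocols import PredictionOutcome
    from .simulator import ReplicateSummary

__all__ = [
    "ValidationResult",
    "GroupComparison",
    "MannWhitneyResult",
    "format_p",
    "poisson_binomial_tail",
    "biased_binomial_test",
    "binomial_all_positive",
    "mann_whitney_exact",
    "compare_conditions",
    "replicate_ci",
    "significance_bucket",
    "write_validation_report",
    "write_comparison_report",
]

#: below this, a p-value is rendered as the printed bound "<0.00000001"
_TINY_P = 1e-8

#: largest pooled sample size for which the Mann-Whitney p is fully enumerated
MW_EXACT_LIMIT = 12


def format_p(p: float, decimals: int = 3) -> str:
    """Printed-precision rendering: round-half-even at ``decimals`` places.

    Values below 1e-8 render as the bound ``"<0.00000001"``.  Full precision
    is always retained alongside in the result objects; this is display only.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value out of range: {p}")
    if p < _TINY_P:
        return "<0.00000001"
    return f"{round(p, decimals):.{decimals}f}"


def poisson_binomial_tail(probs: Sequence[float], k: int) -> float:
    """Exact P(X >= k) for X a sum of independent Bernoulli(p_i).

    Computed by dynamic-programming convolution of the success-count
    distribution, O(N^2); exact up to float rounding.  Reduces to the
    binomial upper tail when the p_i are equal.
    """
    probs = list(probs)
    n = len(probs)
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    dist = np.zeros(n + 1)
    dist[0] = 1.0
    for m, p in enumerate(probs, start=1):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"Bernoulli probability out of range: {p}")
        dist[1 : m + 1] = dist[1 : m + 1] * (1.0 - p) + dist[:m] * p
        dist[0] *= 1.0 - p
    return float(dist[k:].sum())


@dataclass(frozen=True)
class ValidationResult:
    """Bias-compensated binomial panel statistic.

    ``per_prediction_chance`` lists each prediction's chance-success
    probability (p_pos for up-predictions, p_neg for down); ``p_value`` is
    the exact Poisson-binomial upper tail P(at least n_agree chance
    agreements).
    """

    n_predictions: int
    n_agree: int
    per_prediction_chance: tuple[float, ...]
    p_value: float
    p_value_printed: str
    panel: str = ""


def biased_binomial_test(
    outcomes: Sequence["PredictionOutcome"],
    p_pos: float,
    p_neg: Optional[float] = None,
    panel: str = "",
) -> ValidationResult:
    """Exact panel test compensating for the network's prediction bias.

    Each prediction's chance-success probability is ``p_pos`` if its
    predicted direction is up and ``p_neg`` if down (a null prediction, which
    never counts as an agreement, takes the probability of its expected
    direction so the null model stays defined).  The p-value is the exact
    probability of at least the observed number of agreements under
    independent Bernoulli trials with those probabilities — the binomial
    upper tail for homogeneous panels, the Poisson-binomial upper tail in
    general; an all-up all-agree panel gives exactly ``p_pos ** N``.
    """
    if len(outcomes) == 0:
        raise ValueError("empty prediction panel")
    if not (0.0 < p_pos < 1.0):
        raise ValueError(f"p_pos must lie strictly in (0, 1), got {p_pos}")
    if p_neg is None:
        p_neg = 1.0 - p_pos
    if abs(p_pos + p_neg - 1.0) > 1e-12:
        raise ValueError("p_pos and p_neg must sum to 1")

    chances = []
    n_agree = 0
    for o in outcomes:
        direction = o.predicted_direction if o.predicted_direction != "null" else o.expected_direction
        chances.append(p_pos if direction == "up" else p_neg)
        n_agree += bool(o.agree)
    p_value = poisson_binomial_tail(chances, n_agree)
    return ValidationResult(
        n_predictions=len(outcomes),
        n_agree=n_agree,
        per_prediction_chance=tuple(chances),
        p_value=p_value,
        p_value_printed=format_p(p_value),
        panel=panel,
    )


def binomial_all_positive(n: int, p_pos: float) -> float:
    """Chance probability that an all-up panel of size n agrees entirely.

    The closed form ``p_pos ** n`` of the bias-compensated test for a
    homogeneous, all-agree panel of positive-direction predictions.
    """
    if n < 1:
        raise ValueError("panel size must be >= 1")
    if not (0.0 < p_pos < 1.0):
        raise ValueError(f"p_pos must lie strictly in (0, 1), got {p_pos}")
    return p_pos**n


class MannWhitneyResult(NamedTuple):
    U: float
    p_two_sided: float
    exact: bool


def _u_statistic(pooled_ranks: np.ndarray, a_mask: np.ndarray, n_a: int) -> float:
    return float(pooled_ranks[a_mask].sum()) - n_a * (n_a + 1) / 2.0


def mann_whitney_exact(
    a: Sequence[float], b: Sequence[float]
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U with an exact small-sample p-value.

    For pooled sizes up to ``MW_EXACT_LIMIT`` the p-value is computed by full
    enumeration of all C(n_a+n_b, n_a) group assignments of the observed
    (possibly tied, midranked) data: p = P(|U - n_a n_b / 2| >= |U_obs -
    n_a n_b / 2|) under random assignment.  Larger samples fall back to the
    tie-corrected normal approximation and are flagged ``exact=False``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks for ties
    mask = np.zeros(n, dtype=bool)
    mask[:n_a] = True
    u_obs = _u_statistic(ranks, mask, n_a)

    if n <= MW_EXACT_LIMIT:
        mu = n_a * n_b / 2.0
        d_obs = abs(u_obs - mu)
        hits = 0
        total = 0
        for combo in itertools.combinations(range(n), n_a):
            m = np.zeros(n, dtype=bool)
            m[list(combo)] = True
            u = _u_statistic(ranks, m, n_a)
            hits += abs(u - mu) >= d_obs - 1e-9
            total += 1
        return MannWhitneyResult(U=u_obs, p_two_sided=hits / total, exact=True)

    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(U=float(res.statistic), p_two_sided=float(res.pvalue), exact=False)


def significance_bucket(p: float) -> str:
    """Render a p-value in reporting buckets: ns, p<0.05, p<0.01, p<0.001."""
    if p < 0.001:
        return "p<0.001"
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return "ns"


@dataclass(frozen=True)
class GroupComparison:
    """One between-condition Mann-Whitney comparison."""

    concept_id: str
    group_a: tuple[float, ...]
    group_b: tuple[float, ...]
    U: float
    p_two_sided: float
    significant_at: str
    exact: bool


def compare_conditions(
    summary_a: "ReplicateSummary",
    summary_b: "ReplicateSummary",
    concepts: Sequence[str],
    pooling: str = "per_concept",
) -> list[GroupComparison]:
    """Mann-Whitney comparisons of two conditions over a concept panel.

    ``per_concept`` compares each concept's replicate values between the
    conditions (n = replicates per group; note an exact 3-vs-3 test cannot
    fall below p = 0.1).  ``pooled_panel`` pools all listed concepts'
    replicate values per condition into a single comparison, which can reach
    conventional significance from triplicates.
    """
    if summary_a.n_replicates != summary_b.n_replicates:
        raise ValueError(
            f"replicate counts differ: {summary_a.n_replicates} vs "
            f"{summary_b.n_replicates}"
        )
    for c in concepts:
        if c not in summary_a.concept_ids or c not in summary_b.concept_ids:
            raise KeyError(f"concept {c!r} missing from a summary")
    if pooling not in ("per_concept", "pooled_panel"):
        raise ValueError(f"unknown pooling mode {pooling!r}")

    def build(cid: str, va: np.ndarray, vb: np.ndarray) -> GroupComparison:
        mw = mann_whitney_exact(va, vb)
        return GroupComparison(
            concept_id=cid,
            group_a=tuple(map(float, va)),
            group_b=tuple(map(float, vb)),
            U=mw.U,
            p_two_sided=mw.p_two_sided,
            significant_at=significance_bucket(mw.p_two_sided),
            exact=mw.exact,
        )

    if pooling == "per_concept":
        return [
            build(c, summary_a.replicate_values(c), summary_b.replicate_values(c))
            for c in concepts
        ]
    va = np.concatenate([summary_a.replicate_values(c) for c in concepts])
    vb = np.concatenate([summary_b.replicate_values(c) for c in concepts])
    return [build("pooled:" + "+".join(concepts), va, vb)]


def write_validation_report(
    results: Sequence[ValidationResult],
    json_path: str | Path | None = None,
    csv_path: str | Path | None = None,
) -> "pd.DataFrame":
    """Panel-level validation report as a DataFrame, optionally JSON + CSV."""
    import json as _json

    import pandas as pd

    df = pd.DataFrame(
        {
            "panel": [r.panel for r in results],
            "n_predictions": [r.n_predictions for r in results],
            "n_agree": [r.n_agree for r in results],
            "p_value": [r.p_value for r in results],
            "p_printed": [r.p_value_printed for r in results],
        }
    )
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if json_path is not None:
        payload = [
            {
                "panel": r.panel,
                "n_predictions": r.n_predictions,
                "n_agree": r.n_agree,
                "per_prediction_chance": list(r.per_prediction_chance),
                "p_value": r.p_value,
                "p_printed": r.p_value_printed,
            }
            for r in results
        ]
        with open(json_path, "w", encoding="utf-8") as fh:
            _json.dump(payload, fh, indent=1)
            fh.write("\n")
    return df


def write_comparison_report(
    comparisons: Sequence[GroupComparison], csv_path: str | Path | None = None
) -> "pd.DataFrame":
    """Between-condition comparison report (concept, U, p, bucket)."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "concept_id": [c.concept_id for c in comparisons],
            "U": [c.U for c in comparisons],
            "p_two_sided": [c.p_two_sided for c in comparisons],
            "significant_at": [c.significant_at for c in comparisons],
            "exact": [c.exact for c in comparisons],
        }
    )
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    return df


def replicate_ci(
    values: Sequence[float], level: float = 0.95
) -> tuple[float, float, float]:
    """Two-sided t-based confidence interval (mean, low, high).

    A single value yields a degenerate zero-width interval; so do identical
    replicates (sample s.d. 0).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("no values")
    if float(x.min()) == float(x.max()):  # identical replicates: exact zero width
        v = float(x[0])
        return v, v, v
    mean = float(x.mean())
    sem = float(x.std(ddof=1)) / math.sqrt(x.size)
    t_crit = float(sps.t.ppf(0.5 + level / 2.0, df=x.size - 1))
    half = t_crit * sem
    return mean, mean - half, mean + half
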