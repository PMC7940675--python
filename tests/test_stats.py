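"""Panel binomial test, Poisson-binomial tail, Mann-Whitney, CIs."""

import itertools
import math

import numpy as np
import pytest

from fcmsim import (
    PredictionOutcome,
    biased_binomial_test,
    binomial_all_positive,
    compare_conditions,
    format_p,
    mann_whitney_exact,
    poisson_binomial_tail,
    replicate_ci,
    significance_bucket,
)

P_POS = 0.656


def outcome(predicted="up", expected="up", agree=None, mean=0.5):
    if agree is None:
        agree = predicted == expected
    return PredictionOutcome(
        feature_id="x", predicted_direction=predicted,
        expected_direction=expected, agree=agree, mean_activation=mean,
    )


class TestPanelBinomial:
    @pytest.mark.parametrize(
        "n, decimals, printed",
        [
            (3, 3, "0.282"),
            (4, 3, "0.185"),
            (6, 2, "0.08"),
            (7, 3, "0.052"),
            (9, 3, "0.022"),  # 0.656**9 = 0.0225; see methods note
            (10, 3, "0.015"),
            (55, 3, "<0.00000001"),
        ],
    )
    def test_all_agree_panels_print_published_values(self, n, decimals, printed):
        p = binomial_all_positive(n, P_POS)
        assert format_p(p, decimals) == printed
        # the general test reduces to the closed form on these panels
        res = biased_binomial_test([outcome() for _ in range(n)], P_POS)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_single_prediction_gives_p_pos(self):
        res = biased_binomial_test([outcome()], P_POS)
        assert res.p_value == pytest.approx(P_POS)

    def test_strictly_decreasing_in_panel_size(self):
        ps = [binomial_all_positive(n, P_POS) for n in range(1, 30)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_mixed_panel_matches_bernoulli_enumeration(self):
        outcomes = [outcome("up"), outcome("up"), outcome("down", "down")]
        res = biased_binomial_test(outcomes, P_POS)
        probs = [P_POS, P_POS, 1 - P_POS]
        brute = sum(
            math.prod(p if hit else 1 - p for p, hit in zip(probs, pattern))
            for pattern in itertools.product([1, 0], repeat=3)
            if sum(pattern) >= 3
        )
        assert res.p_value == pytest.approx(brute, rel=1e-12)
        assert res.per_prediction_chance == (P_POS, P_POS, 1 - P_POS)

    def test_partial_agreement_upper_tail(self):
        outcomes = [outcome() for _ in range(4)] + [
            outcome("down", "up", agree=False)
        ]
        res = biased_binomial_test(outcomes, P_POS)
        assert res.n_agree == 4
        probs = [P_POS] * 4 + [1 - P_POS]
        assert res.p_value == pytest.approx(poisson_binomial_tail(probs, 4))

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            biased_binomial_test([], P_POS)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.3])
    def test_degenerate_chance_probability_rejected(self, p):
        with pytest.raises(ValueError):
            biased_binomial_test([outcome()], p)
        with pytest.raises(ValueError):
            binomial_all_positive(3, p)


class TestPoissonBinomial:
    def test_tail_at_zero_is_one(self):
        assert poisson_binomial_tail([0.3, 0.9], 0) == pytest.approx(1.0)

    def test_homogeneous_matches_binomial(self):
        from scipy.stats import binom

        assert poisson_binomial_tail([0.4] * 8, 5) == pytest.approx(
            binom.sf(4, 8, 0.4), rel=1e-12
        )

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(10):
            n = int(rng.integers(1, 11))
            probs = rng.uniform(0.05, 0.95, size=n)
            k = int(rng.integers(0, n + 1))
            brute = sum(
                math.prod(p if h else 1 - p for p, h in zip(probs, pat))
                for pat in itertools.product([1, 0], repeat=n)
                if sum(pat) >= k
            )
            assert poisson_binomial_tail(probs, k) == pytest.approx(brute, rel=1e-10)


def pair_count_u(a, b):
    """Independent U oracle: direct greater/tie pair counting."""
    return sum((x > y) + 0.5 * (x == y) for x in a for y in b)


def enumeration_p(a, b):
    """Independent two-sided p oracle over all group reassignments."""
    pooled = list(a) + list(b)
    n_a = len(a)
    mu = n_a * len(b) / 2.0
    d_obs = abs(pair_count_u(a, b) - mu)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        hits += abs(pair_count_u(ga, gb) - mu) >= d_obs - 1e-9
        total += 1
    return hits / total


class TestMannWhitney:
    def test_fully_separated_3v3_reaches_exact_floor(self):
        res = mann_whitney_exact([1, 2, 3], [4, 5, 6])
        assert res.exact
        assert res.p_two_sided == pytest.approx(0.1)  # 2 of C(6,3)=20 splits

    def test_identical_groups_p_one(self):
        res = mann_whitney_exact([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert res.p_two_sided == pytest.approx(1.0)

    def test_swap_antisymmetry(self, rng):
        a = rng.normal(size=4)
        b = rng.normal(size=5)
        r_ab = mann_whitney_exact(a, b)
        r_ba = mann_whitney_exact(b, a)
        assert r_ab.p_two_sided == pytest.approx(r_ba.p_two_sided)
        assert r_ab.U + r_ba.U == pytest.approx(len(a) * len(b))

    def test_invariant_under_monotone_transform(self, rng):
        a = rng.uniform(-1, 1, size=4)
        b = rng.uniform(-1, 1, size=4)
        base = mann_whitney_exact(a, b)
        warped = mann_whitney_exact(np.exp(3 * a), np.exp(3 * b))
        assert warped.U == pytest.approx(base.U)
        assert warped.p_two_sided == pytest.approx(base.p_two_sided)

    def test_matches_enumeration_with_ties(self, rng):
        for _ in range(15):
            n_a = int(rng.integers(1, 5))
            n_b = int(rng.integers(1, 5))
            a = rng.integers(0, 4, size=n_a).astype(float)  # heavy ties
            b = rng.integers(0, 4, size=n_b).astype(float)
            res = mann_whitney_exact(a, b)
            assert res.exact
            assert res.U == pytest.approx(pair_count_u(a, b))
            assert res.p_two_sided == pytest.approx(enumeration_p(a, b))

    def test_large_samples_flagged_approximate(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(1.0, size=10)
        res = mann_whitney_exact(a, b)
        assert not res.exact
        from scipy.stats import mannwhitneyu

        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_two_sided == pytest.approx(ref.pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])


class TestReplicateCI:
    def test_constant_replicates_zero_width(self):
        assert replicate_ci([0.5, 0.5, 0.5]) == (0.5, 0.5, 0.5)

    def test_two_values_symmetric(self):
        mean, low, high = replicate_ci([0.0, 1.0])
        assert mean == 0.5
        assert high - mean == pytest.approx(mean - low)

    def test_triplicate_closed_form(self):
        mean, low, high = replicate_ci([1.0, 2.0, 3.0])
        assert mean == 2.0
        assert high - mean == pytest.approx(2.4841, abs=5e-5)  # t(.975,2)/sqrt(3)

    def test_single_value_degenerate(self):
        assert replicate_ci([0.3]) == (0.3, 0.3, 0.3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            replicate_ci([])


class TestCompareConditions:
    def _summary(self, shift=0.0, replicates=3):
        from fcmsim import ClampSpec, Concept, ConceptNetwork, SimulationConfig
        from fcmsim import Relationship, run_replicates

        ids = [f"F{i}" for i in range(9)]
        net = ConceptNetwork(
            [Concept("S")] + [Concept(i) for i in ids],
            [Relationship("S", i, max(min(0.8 + shift, 1.0), 0.05)) for i in ids],
        )
        cfg = SimulationConfig(max_iterations=60, init_mode="uniform_random",
                               seed=4, replicates=replicates)
        return run_replicates(net, ClampSpec({"S": 1.0}), cfg), ids

    def test_identical_summaries_not_significant(self):
        s, ids = self._summary()
        for c in compare_conditions(s, s, ids, pooling="per_concept"):
            assert c.p_two_sided == pytest.approx(1.0)
            assert c.significant_at == "ns"

    def test_per_concept_triplicates_cannot_reach_significance(self):
        sa, ids = self._summary()
        sb, _ = self._summary(shift=-0.6)
        for c in compare_conditions(sa, sb, ids, pooling="per_concept"):
            assert c.p_two_sided >= 0.1 - 1e-12  # exact 3-vs-3 floor

    def test_pooled_panel_detects_uniform_shift(self):
        sa, ids = self._summary()
        sb, _ = self._summary(shift=-0.6)
        (pooled,) = compare_conditions(sa, sb, ids, pooling="pooled_panel")
        assert pooled.p_two_sided < 0.01
        assert pooled.significant_at in ("p<0.01", "p<0.001")

    def test_mismatched_replicates_rejected(self):
        sa, ids = self._summary()
        sb, _ = self._summary(replicates=4)
        with pytest.raises(ValueError, match="replicate"):
            compare_conditions(sa, sb, ids)

    def test_missing_concept_rejected(self):
        sa, ids = self._summary()
        with pytest.raises(KeyError, match="GHOST"):
            compare_conditions(sa, sa, ["GHOST"])


def test_significance_buckets():
    assert significance_bucket(0.2) == "ns"
    assert significance_bucket(0.04) == "p<0.05"
    assert significance_bucket(0.009) == "p<0.01"
    assert significance_bucket(0.0005) == "p<0.001"


def test_format_p_bounds():
    assert format_p(5e-9) == "<0.00000001"
    with pytest.raises(ValueError):
        format_p(1.2)
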