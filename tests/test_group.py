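"""Quorum group accuracy: exact binomial, simulation, limits, intervals."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quorumpool import (
    BelowChanceError,
    BoundaryQuorumError,
    GroupRule,
    OperatingPoint,
    ValidationError,
    asymptotic_group_accuracy,
    expected_accuracy,
    group_accuracy_exact,
    group_accuracy_sim,
    group_accuracy_sim_cues,
    majority_accuracy_condorcet,
    p_choose_plus,
    quorum_bounds,
    recommend_quorum,
)
from quorumpool.experiments import figure3_panel
from .conftest import enumerate_choose_plus


def pt(a_plus, a_minus):
    return OperatingPoint.from_rates(a_plus, a_minus)


class TestChoosePlusProbability:
    def test_single_voter_decides(self):
        for v in (0.0, 0.3, 1.0):
            assert p_choose_plus(v, GroupRule(n=1, q=0.5)) == pytest.approx(v)

    def test_three_voters_majority(self):
        # P(K >= 2), K ~ Binom(3, 0.6) = 3*0.36*0.4 + 0.216
        assert p_choose_plus(0.6, GroupRule(n=3, q=0.5)) == pytest.approx(0.648, abs=1e-12)

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(
        n=st.integers(1, 12),
        v=st.floats(0.0, 1.0),
        q=st.floats(0.0, 0.999),
        tie_policy=st.sampled_from(["coin_flip", "choose_minus"]),
    )
    def test_matches_full_enumeration(self, n, v, q, tie_policy):
        rule = GroupRule(n=n, q=q, tie_policy=tie_policy)
        assert p_choose_plus(v, rule) == pytest.approx(
            enumerate_choose_plus(v, n, q, tie_policy), abs=1e-12
        )

    def test_tie_policies_differ_by_half_tie_mass(self):
        # n=4, q=0.5: the count 2 ties exactly
        from scipy.stats import binom

        coin = p_choose_plus(0.6, GroupRule(n=4, q=0.5, tie_policy="coin_flip"))
        minus = p_choose_plus(0.6, GroupRule(n=4, q=0.5, tie_policy="choose_minus"))
        assert coin - minus == pytest.approx(0.5 * binom.pmf(2, 4, 0.6), abs=1e-14)

    def test_fractional_quorum_count_has_no_tie(self):
        assert GroupRule(n=5001, q=0.035).tie_count is None
        assert GroupRule(n=1000, q=0.5).tie_count == 500

    def test_rule_validation(self):
        with pytest.raises(ValidationError):
            GroupRule(n=0, q=0.5)
        with pytest.raises(ValidationError):
            GroupRule(n=3, q=1.0)
        with pytest.raises(ValidationError):
            GroupRule(n=3, q=0.5, tie_policy="alphabetical")


class TestExactGroupAccuracy:
    def test_group_of_one_is_the_individual(self):
        point = pt(0.8, 0.6)
        res = group_accuracy_exact(point, 0.3, GroupRule(n=1, q=0.5))
        assert res.accuracy == pytest.approx(expected_accuracy(0.3, point), abs=1e-14)

    def test_decomposition_holds(self):
        res = group_accuracy_exact(pt(0.9, 0.4), 0.7, GroupRule(n=11, q=0.5))
        assert res.accuracy == pytest.approx(0.7 * res.acc_plus + 0.3 * res.acc_minus)

    def test_majority_converges_to_prior_not_one(self, panel_points):
        """With a_plus > 1/2 > a_minus, large majority groups are always
        right in state + and always wrong in state -, so accuracy -> p."""
        _, point = panel_points["a"]
        res = group_accuracy_exact(point, 0.9, GroupRule(n=1001, q=0.5))
        assert res.accuracy == pytest.approx(0.9, abs=0.005)
        assert res.acc_plus > 0.999 and res.acc_minus < 0.001

    def test_quorum_inside_interval_converges_to_one(self, panel_points):
        _, point = panel_points["a"]
        res = group_accuracy_exact(point, 0.9, GroupRule(n=1001, q=0.7))
        assert res.accuracy == pytest.approx(1.0, abs=1e-6)

    def test_matches_classic_condorcet_when_accuracies_equal(self):
        for a in (0.3, 0.5, 0.6, 0.9):
            for n in (1, 4, 7, 20):
                two_error = group_accuracy_exact(pt(a, a), 0.37, GroupRule(n=n, q=0.5))
                assert two_error.accuracy == pytest.approx(
                    majority_accuracy_condorcet(a, n), abs=1e-14
                )


class TestSimulation:
    def test_unanimously_correct_voters(self):
        res = group_accuracy_sim(pt(1.0, 1.0), 0.5, GroupRule(n=9, q=0.8), n_reps=500, seed=7)
        assert res.accuracy == 1.0

    def test_seed_reproducibility(self):
        rule = GroupRule(n=51, q=0.5)
        r1 = group_accuracy_sim(pt(0.9, 0.4), 0.7, rule, n_reps=2000, seed=123)
        r2 = group_accuracy_sim(pt(0.9, 0.4), 0.7, rule, n_reps=2000, seed=123)
        assert r1 == r2
        r3 = group_accuracy_sim(pt(0.9, 0.4), 0.7, rule, n_reps=2000, seed=124)
        assert r3.accuracy != r1.accuracy or r3.acc_plus != r1.acc_plus

    def test_simulation_tracks_exact(self, rng):
        """Simulated accuracy lands within 4 binomial SEs of exact over
        random parameter sets."""
        for i in range(20):
            a_plus = rng.uniform(0.05, 0.99)
            a_minus = rng.uniform(max(0.0, 1 - a_plus) + 0.01, 1.0)
            p = rng.uniform(0.1, 0.9)
            rule = GroupRule(n=int(rng.integers(1, 200)), q=rng.uniform(0.05, 0.95))
            exact = group_accuracy_exact(pt(a_plus, a_minus), p, rule)
            sim = group_accuracy_sim(pt(a_plus, a_minus), p, rule, n_reps=10_000,
                                     seed=int(rng.integers(2**31)))
            se = max(np.sqrt(exact.accuracy * (1 - exact.accuracy) / 10_000), 1e-4)
            assert abs(sim.accuracy - exact.accuracy) <= 4 * se

    def test_cue_level_simulation_agrees(self):
        """Re-drawing Gaussian cues and thresholding voter-by-voter gives
        the same law as drawing correctness from (a_plus, a_minus)."""
        spec = figure3_panel("a")
        rule = GroupRule(n=51, q=0.5)
        from quorumpool import optimal_operating_point

        point = optimal_operating_point(spec.ecology)
        exact = group_accuracy_exact(point, spec.ecology.p, rule)
        sim = group_accuracy_sim_cues(spec.ecology, rule, n_reps=10_000, seed=11)
        se = max(np.sqrt(exact.accuracy * (1 - exact.accuracy) / 10_000), 1e-4)
        assert abs(sim.accuracy - exact.accuracy) <= 4 * se


class TestClassicCondorcet:
    def test_chance_accuracy_stays_at_half(self):
        for n in (1, 3, 11, 101):
            assert majority_accuracy_condorcet(0.5, n) == pytest.approx(0.5, abs=1e-12)

    def test_three_voter_value(self):
        assert majority_accuracy_condorcet(0.6, 3) == pytest.approx(0.648, abs=1e-12)

    def test_monotone_in_group_size(self):
        ns = range(1, 203, 2)
        good = [majority_accuracy_condorcet(0.6, n) for n in ns]
        poor = [majority_accuracy_condorcet(0.4, n) for n in ns]
        assert all(b > a for a, b in zip(good, good[1:]))
        assert all(b < a for a, b in zip(poor, poor[1:]))
        assert good[-1] > 0.99 and poor[-1] < 0.01


class TestAsymptotics:
    def test_quorum_inside_interval_gives_one(self):
        res = asymptotic_group_accuracy(pt(0.9, 0.4), 0.8, q=0.75)
        assert res.accuracy == 1.0 and res.plus_correct and res.minus_correct

    def test_majority_limits_in_mixed_regions(self):
        assert asymptotic_group_accuracy(pt(0.9051, 0.3779), 0.9, 0.5).accuracy == pytest.approx(0.9)
        assert asymptotic_group_accuracy(pt(0.1694, 0.9748), 0.7, 0.5).accuracy == pytest.approx(0.3)

    def test_boundary_quorum_rejected(self):
        with pytest.raises(BoundaryQuorumError):
            asymptotic_group_accuracy(pt(0.7, 0.6), 0.5, q=0.7)
        with pytest.raises(BoundaryQuorumError):
            asymptotic_group_accuracy(pt(0.7, 0.6), 0.5, q=0.4)

    def test_exact_accuracy_approaches_limit(self, rng):
        """Finite-N exact accuracy at N=10001 sits within 0.01 of the
        law-of-large-numbers limit, inside and outside the interval."""
        for _ in range(10):
            a_plus = rng.uniform(0.65, 0.95)
            a_minus = rng.uniform(1.0 - a_plus + 0.08, 0.45)  # above chance, q=1/2 mixed
            p = rng.uniform(0.2, 0.8)
            point = pt(a_plus, a_minus)
            lo, hi = quorum_bounds(point)
            q_in = rng.uniform(lo + 0.02, hi - 0.02)
            for q in (q_in, 0.5):
                limit = asymptotic_group_accuracy(point, p, q).accuracy
                exact = group_accuracy_exact(point, p, GroupRule(n=10_001, q=q)).accuracy
                assert abs(exact - limit) < 0.01


class TestQuorumInterval:
    def test_reference_intervals(self, panel_points):
        _, point_a = panel_points["a"]
        lo, hi = quorum_bounds(point_a)
        assert (lo, hi) == pytest.approx((0.6221, 0.9051), abs=5e-4)
        assert lo < 0.7 < hi  # the panel-b remediation quorum fits

        _, point_e = panel_points["e"]
        lo, hi = quorum_bounds(point_e)
        assert (lo, hi) == pytest.approx((0.0253, 0.1697), abs=5e-4)
        assert lo < 0.035 < hi  # the panel-f remediation quorum fits

    def test_below_chance_and_degenerate_points_rejected(self):
        with pytest.raises(BelowChanceError):
            quorum_bounds(pt(0.3, 0.6))
        with pytest.raises(BelowChanceError):
            quorum_bounds(pt(0.6, 0.4))  # boundary: empty interval

    @pytest.mark.parametrize(
        "a_plus, a_minus, q_mid, label",
        [
            (0.9051, 0.3779, 0.7636, "super_majority"),
            (0.1694, 0.9748, 0.0973, "sub_majority"),
            (0.8, 0.8, 0.5, "majority_compatible"),
        ],
    )
    def test_recommendation(self, a_plus, a_minus, q_mid, label):
        q, got = recommend_quorum(pt(a_plus, a_minus))
        assert q == pytest.approx(q_mid, abs=5e-4)
        assert got == label

    def test_recommended_quorum_is_asymptotically_perfect(self, rng):
        for _ in range(25):
            a_plus = rng.uniform(0.05, 0.95)
            a_minus = rng.uniform(max(0.0, 1 - a_plus) + 0.02, 1.0)
            point = pt(a_plus, a_minus)
            q, _ = recommend_quorum(point)
            assert asymptotic_group_accuracy(point, 0.5, q).accuracy == 1.0
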