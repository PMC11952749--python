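import numpy as np
import pytest

from pursuitval import (
    ForgoWorld,
    MisestimationSpec,
    OutsideContext,
    Pursuit,
    behavior_triplet,
    brute_force_optimal_accept_set,
    choice_decision,
    critical_outside_rate_for_choice,
    critical_outside_time_for_choice,
    forgo_decision,
    global_rate_forgo_world,
    global_rate_in_out,
    optimal_accept_set,
    policy_region_map,
    preference_reversal_delay,
    subjective_value_in_out,
)
from .conftest import random_pursuit_context


class TestForgo:
    def test_take_when_inside_rate_higher(self):
        assert forgo_decision(Pursuit(2.5, 2.5), OutsideContext.from_rate(0.8, 6)) == "take"

    def test_forgo_when_outside_rate_higher(self):
        assert forgo_decision(Pursuit(2.5, 2.5), OutsideContext.from_rate(1.3, 6)) == "forgo"

    def test_indifferent_at_equal_rates(self):
        assert forgo_decision(Pursuit(3, 3), OutsideContext(5, 5)) == "indifferent"

    def test_agrees_with_sv_sign(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            pursuit, outside = random_pursuit_context(rng)
            decision = forgo_decision(pursuit, outside)
            sv = subjective_value_in_out(pursuit, outside).subjective_value
            if decision == "take":
                assert sv > 0
            elif decision == "forgo":
                assert sv < 0
            else:
                assert sv == pytest.approx(0.0, abs=1e-6)


class TestOptimalAcceptSet:
    def test_drops_rate_diluting_pursuit(self):
        world = ForgoWorld((Pursuit(1, 1, "A"), Pursuit(0.2, 1, "B")), (1.0, 1.0), 0.0)
        accepted = optimal_accept_set(world)
        assert accepted == frozenset({0})
        assert global_rate_forgo_world(world, accepted) == pytest.approx(0.5)

    def test_single_positive_pursuit_accepted(self):
        world = ForgoWorld((Pursuit(2, 1),), (0.5,), 0.0)
        assert optimal_accept_set(world) == frozenset({0})

    def test_matches_exhaustive_search(self, random_worlds):
        for world in random_worlds(40, 8, seed=101):
            accepted = optimal_accept_set(world)
            best_set, best_rate = brute_force_optimal_accept_set(world)
            assert global_rate_forgo_world(world, accepted) == pytest.approx(
                best_rate, rel=1e-9, abs=1e-12
            )
            assert accepted == best_set


class TestChoice:
    def test_prefers_ll_with_no_outside_reward(self, ss_ll_short):
        ss, ll, t_out = ss_ll_short
        assert choice_decision(ss, ll, OutsideContext.from_rate(0.0, t_out)) == "LL"

    def test_prefers_ss_at_moderate_outside_rate(self, ss_ll_short):
        ss, ll, t_out = ss_ll_short
        assert choice_decision(ss, ll, OutsideContext.from_rate(0.4, t_out)) == "SS"

    def test_identical_pursuits_indifferent(self):
        p = Pursuit(3, 4)
        assert choice_decision(p, p, OutsideContext(1, 2)) == "indifferent"

    def test_three_decision_rules_agree(self):
        """Global-rate, marginal-rate, and sv comparisons give one policy."""
        rng = np.random.default_rng(23)
        checked = 0
        while checked < 500:
            ss, outside = random_pursuit_context(rng)
            ll = Pursuit(ss.reward + rng.uniform(0.1, 5), ss.duration + rng.uniform(0.1, 10))
            rate_ss = global_rate_in_out(ss, outside)
            rate_ll = global_rate_in_out(ll, outside)
            if abs(rate_ll - rate_ss) < 1e-6:
                continue
            by_rate = choice_decision(ss, ll, outside)
            marginal = (ll.reward - ss.reward) / (ll.duration - ss.duration)
            best = max(rate_ss, rate_ll)
            by_marginal = "LL" if marginal > best else "SS"
            sv_ss = subjective_value_in_out(ss, outside).subjective_value
            sv_ll = subjective_value_in_out(ll, outside).subjective_value
            by_sv = "LL" if sv_ll > sv_ss else "SS"
            assert by_rate == by_marginal == by_sv
            checked += 1


class TestBehaviorTriplet:
    @pytest.mark.parametrize(
        "rho_out,expected",
        [
            (0.0, ("LL", "take", "take")),
            (0.4, ("SS", "take", "take")),
            (0.8, ("SS", "forgo", "take")),
            (1.3, ("SS", "forgo", "forgo")),
        ],
    )
    def test_optimal_transitions(self, ss_ll_short, rho_out, expected):
        ss, ll, t_out = ss_ll_short
        trip = behavior_triplet(ss, ll, OutsideContext.from_rate(rho_out, t_out))
        assert trip.astuple() == expected

    def test_malapportioned_agent_turns_impatient(self, ss_ll_misest):
        ss, ll, t_out = ss_ll_misest
        outside = OutsideContext.from_rate(0.3, t_out)
        optimal = behavior_triplet(ss, ll, outside)
        assert optimal.astuple() == ("LL", "take", "take")
        spec = MisestimationSpec("outside_both_rate_preserved", 0.3)
        assert behavior_triplet(ss, ll, outside, spec).astuple() == ("SS", "take", "take")


class TestCriticalRate:
    def test_reference_value(self, ss_ll_short):
        ss, ll, t_out = ss_ll_short
        assert critical_outside_rate_for_choice(ss, ll, t_out) == pytest.approx(6.25 / 36)

    def test_equal_rewards_have_no_nonnegative_crossing(self):
        assert critical_outside_rate_for_choice(Pursuit(3, 2), Pursuit(3, 5), 6.0) is None

    def test_choice_flips_across_threshold(self, ss_ll_short):
        ss, ll, t_out = ss_ll_short
        rho = critical_outside_rate_for_choice(ss, ll, t_out)
        assert choice_decision(ss, ll, OutsideContext.from_rate(rho - 1e-6, t_out)) == "LL"
        assert choice_decision(ss, ll, OutsideContext.from_rate(rho + 1e-6, t_out)) == "SS"


class TestCriticalTime:
    def test_self_consistency(self, ss_ll_delay):
        ss, ll, outside = ss_ll_delay
        t_star = critical_outside_time_for_choice(ss, ll, outside.outside_reward)
        assert t_star is not None
        ctx = OutsideContext(outside.outside_reward, t_star)
        sv_ss = subjective_value_in_out(ss, ctx).subjective_value
        sv_ll = subjective_value_in_out(ll, ctx).subjective_value
        assert sv_ss == pytest.approx(sv_ll, abs=1e-9)

    def test_zero_outside_reward_closed_form(self):
        ss, ll = Pursuit(2, 3), Pursuit(5, 12.6)
        t_star = critical_outside_time_for_choice(ss, ll, 0.0)
        expected = (ll.reward * ss.duration - ss.reward * ll.duration) / (ss.reward - ll.reward)
        assert t_star == pytest.approx(expected, abs=1e-8)

    def test_identical_pursuits_have_no_crossing(self):
        p = Pursuit(3, 4)
        assert critical_outside_time_for_choice(p, p, 0.5) is None


class TestPreferenceReversal:
    def test_reference_delay(self, ss_ll_delay):
        assert preference_reversal_delay(*ss_ll_delay) == pytest.approx(6.4)

    def test_choice_flips_across_delay(self, ss_ll_delay):
        ss, ll, outside = ss_ll_delay
        d = preference_reversal_delay(ss, ll, outside)
        assert choice_decision(ss.delayed(d - 1e-6), ll.delayed(d - 1e-6), outside) == "SS"
        assert choice_decision(ss.delayed(d + 1e-6), ll.delayed(d + 1e-6), outside) == "LL"

    def test_equal_rewards_never_reverse(self):
        assert preference_reversal_delay(Pursuit(3, 2), Pursuit(3, 8), OutsideContext(1, 4)) is None


class TestRegionMap:
    def test_optimal_row_reproduces_transitions(self, ss_ll_short):
        ss, ll, t_out = ss_ll_short
        rm = policy_region_map(ss, ll, t_out, [0.0, 0.4, 0.8, 1.3])
        got = list(zip(rm.table.choice, rm.table.forgo_ll, rm.table.forgo_ss))
        assert got == [
            ("LL", "take", "take"),
            ("SS", "take", "take"),
            ("SS", "forgo", "take"),
            ("SS", "forgo", "forgo"),
        ]
        assert len(rm.boundaries) == 3

    def test_transition_order_is_monotone(self, ss_ll_misest):
        ss, ll, t_out = ss_ll_misest
        rm = policy_region_map(ss, ll, t_out, np.linspace(0.001, 1.2, 240))
        trips = [t for t in zip(rm.table.choice, rm.table.forgo_ll, rm.table.forgo_ss)]
        distinct = [trips[0]]
        for t in trips[1:]:
            if t != distinct[-1]:
                distinct.append(t)
        assert distinct == [
            ("LL", "take", "take"),
            ("SS", "take", "take"),
            ("SS", "forgo", "take"),
            ("SS", "forgo", "forgo"),
        ]
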