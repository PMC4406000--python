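import numpy as np
import pytest

from pggtwin import (
    GameConfig,
    Population,
    SimulationPlan,
    STUDY2_GAME,
    StrategyProfile,
    TwinPair,
    conditional_response,
    exhaustive_one_shot,
    make_fixture,
    round_payoffs,
    simulate_iterated,
    simulate_one_shot,
)


def identity_cc(ident="cc", uc=20):
    return StrategyProfile(ident, uc, {k: k for k in range(21)}, "study2")


class TestRoundPayoffs:
    def test_full_cooperation_doubles_endowment(self):
        assert np.allclose(round_payoffs([20] * 4, STUDY2_GAME), 40.0)

    def test_no_cooperation_keeps_endowment(self):
        assert np.allclose(round_payoffs([0] * 4, STUDY2_GAME), 20.0)

    def test_lone_contributor_study1_multiplier(self):
        game = GameConfig(multiplier=1.6)
        p = round_payoffs([20, 0, 0, 0], game)
        assert p[0] == pytest.approx(8.0)
        assert np.allclose(p[1:], 28.0)

    def test_out_of_range_contribution_rejected(self):
        with pytest.raises(ValueError):
            round_payoffs([21, 0, 0, 0], STUDY2_GAME)

    def test_dominance_own_contribution_lowers_own_payoff(self):
        # mpcr < 1: each extra contributed point costs 1 - m/n
        others = [7, 3, 12]
        payoffs = [round_payoffs([c] + others, STUDY2_GAME)[0] for c in range(21)]
        assert all(a > b for a, b in zip(payoffs, payoffs[1:]))

    def test_conservation_identity(self):
        game = STUDY2_GAME
        c = np.array([3, 17, 0, 9], dtype=float)
        p = round_payoffs(c, game)
        assert p.sum() == pytest.approx(
            game.group_size * game.endowment + (game.multiplier - 1) * c.sum(), abs=1e-9
        )


class TestConditionalResponse:
    def test_third_averages_round_half_up(self):
        prof = identity_cc()
        assert conditional_response(prof, 13 + 1 / 3) == 13
        assert conditional_response(prof, 13 + 2 / 3) == 14

    def test_exact_level_returned_directly(self):
        assert conditional_response(identity_cc(), 7.0) == 7

    def test_study1_clamps_level_zero_to_c1(self):
        prof = StrategyProfile("s1", 0, {k: k + 10 for k in range(1, 21)}, "study1")
        assert conditional_response(prof, 1 / 3) == 11  # level 0 -> clamped to C1

    def test_half_rounding_rules_differ_at_halves(self):
        prof = identity_cc()
        assert conditional_response(prof, 6.5, "half_up") == 7
        assert conditional_response(prof, 6.5, "half_even") == 6


class TestOneShot:
    def test_all_zero_population_payoff_is_endowment(self):
        profs = [
            StrategyProfile(f"z{i}", 0, {k: 0 for k in range(21)}, "study2")
            for i in range(4)
        ]
        pop = Population(profs, [TwinPair("p1", "MZ", ("z0", "z1")), TwinPair("p2", "MZ", ("z2", "z3"))])
        res = simulate_one_shot(pop, plan=SimulationPlan(n_groups=500, seed=0))
        for r in res.records:
            assert r.uncond_mean == pytest.approx(20.0)
            assert r.cond_mean == pytest.approx(20.0)
            assert r.total == pytest.approx(40.0)

    def test_role_counts_follow_binomial_sampling(self, oracle_pop):
        n_groups = 40_000
        res = simulate_one_shot(oracle_pop, plan=SimulationPlan(n_groups=n_groups, seed=3))
        n = len(oracle_pop)
        p_cond = 1 / n
        sd_cond = np.sqrt(n_groups * p_cond * (1 - p_cond))
        p_unc = 3 / n
        sd_unc = np.sqrt(n_groups * p_unc * (1 - p_unc))
        for r in res.records:
            assert abs(r.cond_count - n_groups * p_cond) < 4 * sd_cond
            assert abs(r.uncond_count - n_groups * p_unc) < 4 * sd_unc

    def test_seed_determinism_and_sensitivity(self, oracle_pop):
        plan = SimulationPlan(n_groups=2_000, seed=7)
        a = simulate_one_shot(oracle_pop, plan=plan)
        b = simulate_one_shot(oracle_pop, plan=plan)
        assert a.records == b.records
        c = simulate_one_shot(oracle_pop, plan=SimulationPlan(n_groups=2_000, seed=8))
        assert a.records != c.records

    def test_population_smaller_than_group_rejected(self):
        profs = [identity_cc(f"c{i}") for i in range(3)]
        pop = Population(profs, [TwinPair("p1", "MZ", ("c0", "c1")), TwinPair("p2", "MZ", ("c2",))])
        with pytest.raises(ValueError, match="smaller"):
            simulate_one_shot(pop, plan=SimulationPlan(n_groups=10, seed=0))

    def test_matches_exhaustive_oracle_within_mc_error(self, oracle_pop):
        exact = exhaustive_one_shot(oracle_pop)
        sim = simulate_one_shot(oracle_pop, plan=SimulationPlan(n_groups=30_000, seed=5))
        for r, e, su, sc in zip(sim.records, exact, sim.uncond_sem, sim.cond_sem):
            assert abs(r.uncond_mean - e.uncond_mean) < 4 * su
            assert abs(r.cond_mean - e.cond_mean) < 4 * sc


class TestExhaustive:
    def test_four_profiles_single_subset_exact(self):
        profs = [identity_cc(f"c{i}") for i in range(3)] + [
            StrategyProfile("fr", 0, {k: 0 for k in range(21)}, "study2")
        ]
        pop = Population(profs, [TwinPair("p1", "MZ", ("c0", "c1")), TwinPair("p2", "MZ", ("c2", "fr"))])
        recs = exhaustive_one_shot(pop)
        # responder counted once per role assignment: 4 assignments, 1 subset
        assert all(r.cond_count == 1 and r.uncond_count == 3 for r in recs)
        # cc as responder: others (cc,cc,fr) average 40/3 -> level 13, contributes 13
        # payoffs: members (13,20,20,0) -> cc responder: 20-13+26.5 = 33.5
        assert recs[0].cond_mean == pytest.approx(33.5)

    def test_identical_profiles_symmetric(self):
        profs = [identity_cc(f"c{i}") for i in range(5)]
        pop = Population(profs, [TwinPair("p1", "MZ", ("c0", "c1")),
                                 TwinPair("p2", "MZ", ("c2", "c3")),
                                 TwinPair("p3", "MZ", ("c4",))])
        recs = exhaustive_one_shot(pop)
        assert len({round(r.total, 9) for r in recs}) == 1

    def test_enumeration_guard(self):
        pop = make_fixture("cc75_fr25", n=16)
        with pytest.raises(ValueError, match="enumerate"):
            exhaustive_one_shot(pop)


class TestIterated:
    def test_homogeneous_conditional_cooperators_fixed_point(self):
        pop = make_fixture("homogeneous_cc")
        res = simulate_iterated(pop, plan=SimulationPlan(n_groups=300, iterations=5, seed=1))
        assert np.allclose(res.per_round_mean, 40.0, equal_nan=False)

    def test_all_free_riders_stay_at_endowment(self):
        profs = [
            StrategyProfile(f"f{i}", 0, {k: 0 for k in range(21)}, "study2")
            for i in range(6)
        ]
        pop = Population(
            profs,
            [TwinPair(f"p{i}", "MZ", (f"f{2*i}", f"f{2*i+1}")) for i in range(3)],
        )
        res = simulate_iterated(pop, plan=SimulationPlan(n_groups=200, iterations=4, seed=2))
        assert np.allclose(res.per_round_mean, 20.0)

    def test_hand_traced_three_cc_one_fr(self):
        """Fixed group of 3 perfect conditional cooperators + 1 free rider:
        round 1 payoffs (30,30,30,50); CCs respond to level 13 in round 2
        giving (26.5, 26.5, 26.5, 39.5); per-round means 28.25 / 44.75."""
        pop = make_fixture("three_cc_one_fr")
        res = simulate_iterated(pop, plan=SimulationPlan(n_groups=10, iterations=2, seed=0))
        means = [r.mean_payoff_per_round for r in res.records]
        assert means == pytest.approx([28.25, 28.25, 28.25, 44.75])
        assert res.per_round_mean[0].tolist() == pytest.approx([30.0, 26.5])
        assert res.per_round_mean[3].tolist() == pytest.approx([50.0, 39.5])

    def test_conservation_every_round(self, mixed_pop):
        game = mixed_pop.game
        plan = SimulationPlan(n_groups=3_000, iterations=10, seed=4)
        res = simulate_iterated(mixed_pop, plan=plan)
        expected = (
            plan.n_groups * game.group_size * game.endowment
            + (game.multiplier - 1) * res.round_total_contribution
        )
        assert np.max(np.abs(expected - res.round_total_payoff)) < 1e-6

    def test_iterated_requires_at_least_two_rounds(self, oracle_pop):
        with pytest.raises(ValueError):
            simulate_iterated(oracle_pop, plan=SimulationPlan(n_groups=10, iterations=1))

    def test_seed_determinism(self, mixed_pop):
        plan = SimulationPlan(n_groups=1_000, iterations=3, seed=11)
        a = simulate_iterated(mixed_pop, plan=plan)
        b = simulate_iterated(mixed_pop, plan=plan)
        assert np.array_equal(a.per_round_mean, b.per_round_mean, equal_nan=True)
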