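"""Markov cohort engine: transition arithmetic, reward accrual, conservation,
and agreement with an independent individual-level microsimulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osas_cea import (
    LifeTable,
    Strategy,
    adjust_mortality_odds,
    build_transition_matrix,
    cycle_reward,
    discount_factor,
    evaluate_strategy_tree,
    random_parameter_scenario,
    run_cohort,
    run_strategy,
)
from osas_cea.fixtures import scenario_seeds
from osas_cea.markov import ALL_STATES, cessation_rate


class TestAdjustMortalityOdds:
    def test_identity_odds_ratio(self):
        assert adjust_mortality_odds(0.005, 1.0) == pytest.approx(0.005)

    def test_hand_computed_adjustment(self):
        # odds 0.005/0.995 = 0.0050251; x2.87 = 0.0144221; back to probability
        assert adjust_mortality_odds(0.005, 2.87) == pytest.approx(0.014217, abs=1e-6)

    def test_zero_hazard_invariant(self):
        assert adjust_mortality_odds(0.0, 2.87) == 0.0

    def test_degenerate_probability_rejected(self):
        with pytest.raises(ValueError):
            adjust_mortality_odds(1.0, 2.0)
        with pytest.raises(ValueError):
            adjust_mortality_odds(0.5, 0.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(p=st.floats(0.0, 0.99), odds_ratio=st.floats(0.01, 50.0))
    def test_stays_a_probability_and_order_preserving(self, p, odds_ratio):
        adjusted = adjust_mortality_odds(p, odds_ratio)
        assert 0.0 <= adjusted < 1.0
        if odds_ratio > 1 and p > 0:
            assert adjusted > p


class TestCessationAndDiscount:
    def test_first_year_higher_cessation(self, base_params):
        assert cessation_rate(base_params, 1) == 0.10
        for k in (2, 3, 4, 5):
            assert cessation_rate(base_params, k) == 0.06

    def test_perfect_compliance_scenario(self, base_params):
        p = base_params.with_overrides(cpap_cessation_year1=0.0, cpap_cessation_later=0.0)
        assert all(cessation_rate(p, k) == 0.0 for k in range(1, 6))

    def test_cycle_out_of_range(self, base_params):
        with pytest.raises(ValueError):
            cessation_rate(base_params, 0)
        with pytest.raises(ValueError):
            cessation_rate(base_params, 6)

    def test_discount_factors(self):
        assert discount_factor(0.0, 3) == 1.0
        assert discount_factor(0.03, 1) == pytest.approx(0.970874, abs=1e-6)
        assert discount_factor(0.05, 2) == pytest.approx(0.907029, abs=1e-6)


class TestTransitionMatrix:
    def test_zero_mortality_first_cycle_treated_row(self, immortal_params):
        t = build_transition_matrix(immortal_params, 1)
        assert t[0, 0] == pytest.approx(0.90)  # stay treated
        assert t[0, 1] == pytest.approx(0.10)  # quit to untreated

    def test_dead_state_absorbing(self, base_params):
        for k in (1, 3, 5):
            t = build_transition_matrix(base_params, k)
            assert t[4, 4] == 1.0
            assert t[4, :4].sum() == 0.0

    def test_untreated_mortality_odds_adjusted(self, base_params):
        t = build_transition_matrix(base_params, 1)
        assert t[1, 4] == pytest.approx(0.014217, abs=1e-6)

    def test_rows_stochastic_across_cycles(self, base_params):
        for k in range(1, 6):
            t = build_transition_matrix(base_params, k)
            np.testing.assert_allclose(t.sum(axis=1), 1.0, atol=1e-15)
            assert (t >= 0).all()


class TestCycleReward:
    def test_treated_first_year(self, base_params):
        assert cycle_reward("osas_treated", 1, base_params) == (1275.0, 0.55)

    def test_treated_later_years(self, base_params):
        assert cycle_reward("osas_treated", 3, base_params) == (1225.0, 0.55)

    def test_untreated_and_healthy(self, base_params):
        assert cycle_reward("osas_untreated", 3, base_params) == (1800.0, 0.32)
        assert cycle_reward("no_osas", 2, base_params) == (0.0, 0.435)
        assert cycle_reward("no_osas_treated", 1, base_params) == (1275.0, 0.32)

    def test_dead_accrues_nothing(self, base_params):
        assert cycle_reward("dead", 1, base_params) == (0.0, 0.0)


class TestRunCohort:
    def test_forced_arithmetic_all_untreated(self, immortal_params):
        # no deaths, no discounting: 5 years x (0.32 QALY, EUR 1800)
        p = immortal_params.with_overrides(discount_rate=0.0)
        alloc = evaluate_strategy_tree(Strategy("no_screening"), p)
        res = run_cohort(
            type(alloc)(occupancy={"osas_untreated": 1.0, "no_osas": 0.0,
                                   "osas_treated": 0.0, "no_osas_treated": 0.0},
                        upfront_cost=0.0),
            p,
        )
        assert res.total_qaly == pytest.approx(5 * 0.32)
        assert res.total_cost == pytest.approx(5 * 1800)

    def test_fully_treated_compliant_cohort(self, immortal_params):
        p = immortal_params.with_overrides(
            discount_rate=0.0, cpap_cessation_year1=0.0, cpap_cessation_later=0.0
        )
        from osas_cea import InitialAllocation

        res = run_cohort(
            InitialAllocation(
                occupancy={"osas_treated": 1.0, "osas_untreated": 0.0,
                           "no_osas": 0.0, "no_osas_treated": 0.0},
                upfront_cost=0.0,
            ),
            p,
        )
        assert res.total_qaly == pytest.approx(5 * 0.55)

    def test_zero_horizon_returns_upfront_only(self, base_params):
        p = base_params.with_overrides(horizon_years=0)
        res = run_strategy(Strategy("without_cp"), p)
        assert res.total_qaly == 0.0
        assert res.total_cost == pytest.approx(res.upfront_cost)

    def test_totals_decompose_into_per_cycle(self, base_params):
        res = run_strategy(Strategy("with_cp"), base_params)
        assert res.total_cost == pytest.approx(
            res.upfront_cost + sum(c for c, _ in res.per_cycle)
        )
        assert res.total_qaly == pytest.approx(sum(q for _, q in res.per_cycle))

    def test_qaly_monotone_in_mortality_and_utility(self, base_params):
        base = run_strategy(Strategy("with_cp"), base_params).total_qaly
        worse_or = base_params.with_overrides(or_mortality_untreated=7.51)
        better_u = base_params.with_overrides(u_osas_treated=0.70)
        assert run_strategy(Strategy("with_cp"), worse_or).total_qaly < base
        assert run_strategy(Strategy("with_cp"), better_u).total_qaly > base

    def test_immortal_cohort_conserves_live_occupancy(self, immortal_params):
        res = run_strategy(Strategy("with_cp"), immortal_params)
        live = res.trace.occupancy[:, :4].sum(axis=1)
        np.testing.assert_allclose(live, 1.0, atol=1e-12)

    def test_trace_conservation_over_random_scenarios(self):
        for seed in scenario_seeds(2024, 1000):
            params = random_parameter_scenario(seed)
            res = run_strategy(Strategy("with_cp"), params)
            rows = res.trace.occupancy.sum(axis=1)
            np.testing.assert_allclose(rows, 1.0, atol=1e-12)
            dead = res.trace.occupancy[:, 4]
            assert (np.diff(dead) >= -1e-15).all()

    def test_trace_export(self, base_params, tmp_path):
        import pandas as pd

        res = run_strategy(Strategy("without_cp"), base_params)
        path = tmp_path / "trace.csv"
        res.export_trace(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["cycle", *ALL_STATES, "discounted_cost", "discounted_qaly"]
        assert len(df) == base_params.horizon_years + 1
        assert df["discounted_cost"].sum() == pytest.approx(res.total_cost)


class TestMicrosimulationOracle:
    """Individual-level simulation with the same per-cycle probabilities must
    reproduce the cohort expectations within Monte Carlo error."""

    N = 200_000

    def test_agrees_within_three_standard_errors(self, base_params):
        params = base_params
        strat = Strategy("with_cp")
        cohort = run_strategy(strat, params)
        alloc = evaluate_strategy_tree(strat, params)

        rng = np.random.default_rng(20240601)
        probs = np.array([alloc.occupancy[s] for s in ALL_STATES[:4]] + [0.0])
        states = rng.choice(5, size=self.N, p=probs)

        costs = np.full(self.N, alloc.upfront_cost)
        qalys = np.zeros(self.N)
        for k in range(1, params.horizon_years + 1):
            t = build_transition_matrix(params, k)
            reward = np.array([cycle_reward(s, k, params) for s in ALL_STATES])
            d = discount_factor(params.discount_rate, k)
            # begin-of-cycle accrual: reward on the state entering the cycle
            costs += reward[states, 0] * d
            qalys += reward[states, 1] * d
            cum = t.cumsum(axis=1)[states]
            states = (rng.random(self.N)[:, None] > cum).sum(axis=1)

        for sim, expect in ((costs, cohort.total_cost), (qalys, cohort.total_qaly)):
            se = sim.std(ddof=1) / np.sqrt(self.N)
            assert abs(sim.mean() - expect) < 3 * se
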