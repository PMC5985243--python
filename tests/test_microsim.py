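"""Microsimulation engine: state dynamics, accrual accounting, pairing."""

import numpy as np
import pytest

from avcea.cohort import (
    CohortTables,
    build_age_distribution,
    build_mortality_table,
    build_vehicle_lifetable,
)
from avcea.microsim import HealthState, run_iteration, run_simulation
from avcea.parameters import ParameterSet
from avcea.strategy import Strategy

DRIVING = (HealthState.DRIVING, HealthState.DRIVING_INJURED)


def make_cohort(age=47, mortality_spec=None, vehicle_spec=None):
    return CohortTables(
        build_age_distribution({"weights": {age: 1.0}}),
        build_mortality_table(mortality_spec),
        build_vehicle_lifetable(vehicle_spec or {"lifespan": 15}),
    )


def immortal_until_closure():
    return {"table": {0: 0.0, 110: 1.0}}


class TestSinglePathEdges:
    def test_forced_death_in_first_year(self, params):
        """Certain lifetable death at t=0: one undiscounted year lived,
        cost is purchase + one year's recurring + the funeral."""
        p = params.with_values({
            "prob_crash_hpv": 0.0,
            "healthy_utility": 1.0,
        })
        cohort = make_cohort(mortality_spec={"table": {0: 1.0}})
        res = run_simulation([Strategy.HPV], p, cohort, n_iterations=8, seed=0)
        from avcea.costs import build_cost_schedule

        sched = build_cost_schedule(Strategy.HPV, p)
        expected = sched.purchase + sched.annual_recurring + sched.funeral
        np.testing.assert_allclose(res.qalys[Strategy.HPV], 1.0)
        np.testing.assert_allclose(res.cost[Strategy.HPV], expected)

    def test_certain_fatal_crash_in_first_year(self, params):
        p = params.with_values({
            "prob_crash_hpv": 1.0,
            "split_pdo_hpv": 0.0,
            "split_minor_hpv": 0.0,
            "split_severe_hpv": 0.0,
            "split_fatal_hpv": 1.0,
        })
        cohort = make_cohort(mortality_spec=immortal_until_closure())
        res = run_simulation([Strategy.HPV], p, cohort, n_iterations=8, seed=0)
        from avcea.costs import build_cost_schedule

        sched = build_cost_schedule(Strategy.HPV, p)
        expected = (
            sched.purchase + sched.annual_recurring
            + sched.crash_costs[3] + sched.funeral
        )
        np.testing.assert_allclose(res.cost[Strategy.HPV], expected)
        np.testing.assert_allclose(
            res.qalys[Strategy.HPV], p.constants.healthy_utility
        )
        assert (res.death_time[Strategy.HPV] == 0).all()

    def test_vehicle_expiry_moves_to_post_horizon(self, params):
        """With a deterministic 5-year car and no mortality until closure,
        vehicle costs stop after 5 payments while QALYs continue."""
        p = params.with_values({
            "prob_crash_hpv": 0.0,
            "discount_rate": 0.0,
            "healthy_utility": 1.0,
        })
        cohort = make_cohort(
            age=47,
            mortality_spec=immortal_until_closure(),
            vehicle_spec={"lifespan": 5},
        )
        res = run_simulation(
            [Strategy.HPV], p, cohort, n_iterations=4, seed=0, trace=True
        )
        from avcea.costs import build_cost_schedule

        sched = build_cost_schedule(Strategy.HPV, p)
        expected_cost = sched.purchase + 5 * sched.annual_recurring
        np.testing.assert_allclose(res.cost[Strategy.HPV], expected_cost)
        np.testing.assert_allclose(res.qalys[Strategy.HPV], 110 - 47 + 1)
        states = res.traces[Strategy.HPV].states
        assert (states[:, 5] == HealthState.POST_HORIZON_HEALTHY).all()


class TestPairingAndDeterminism:
    def test_same_seed_bitwise_identical(self, params, cohort):
        a = run_simulation([Strategy.HPV, Strategy.AV], params, cohort,
                           n_iterations=500, seed=99)
        b = run_simulation([Strategy.HPV, Strategy.AV], params, cohort,
                           n_iterations=500, seed=99)
        for s in a.strategies:
            np.testing.assert_array_equal(a.cost[s], b.cost[s])
            np.testing.assert_array_equal(a.qalys[s], b.qalys[s])

    def test_identical_inputs_give_identical_arms(self, params, cohort):
        """Two strategies with the same schedule and crash profile share all
        random streams, so their histories coincide exactly."""
        p = params.with_values({
            "cost_vehicle_taxi_hpv": params.value("cost_vehicle_hpv"),
            "cost_taxi_salary": 0.0,
            "cost_parking_spot_taxi": {
                "low": 0,
                "base": params.value("cost_parking_spot")
                * params.value("parking_spot_ratio"),
                "high": 1e9,
            },
            "cost_productivity_annual": 0.0,
        })
        res = run_simulation([Strategy.HPV, Strategy.HPT], p, cohort,
                             n_iterations=300, seed=21)
        np.testing.assert_array_equal(
            res.cost[Strategy.HPV], res.cost[Strategy.HPT]
        )
        np.testing.assert_array_equal(
            res.qalys[Strategy.HPV], res.qalys[Strategy.HPT]
        )

    def test_paired_iteration_shares_start_age(self, params, cohort, rng):
        rec = run_iteration((Strategy.HPV, Strategy.AV), params, cohort, rng)
        assert 16 <= rec.start_age <= 90
        assert set(rec.arms) == {Strategy.HPV, Strategy.AV}
        for arm in rec.arms.values():
            assert arm["cost"] > 0 and arm["qalys"] >= 0

    def test_single_iteration_equals_its_mean(self, params, cohort):
        res = run_simulation([Strategy.HPV], params, cohort,
                             n_iterations=1, seed=4)
        assert res.mean_cost(Strategy.HPV) == res.cost[Strategy.HPV][0]


class TestStateDynamics:
    def test_dead_is_absorbing(self, params, cohort):
        res = run_simulation([Strategy.HPV], params, cohort,
                             n_iterations=3_000, seed=8, trace=True)
        states = res.traces[Strategy.HPV].states
        was_dead = states[:, :-1] == HealthState.DEAD
        assert (states[:, 1:][was_dead] == HealthState.DEAD).all()

    def test_everyone_dead_by_final_timestep(self, params, cohort):
        res = run_simulation([Strategy.HPV], params, cohort,
                             n_iterations=3_000, seed=8, trace=True)
        assert (res.traces[Strategy.HPV].states[:, -1] == HealthState.DEAD).all()

    def test_raising_crash_probability_never_raises_qalys(self, params, cohort):
        """With shared uniforms, a higher annual crash probability yields a
        crash-event superset, so per-iteration QALYs are non-increasing."""
        previous = None
        for prob in (0.0646, 0.2, 0.5, 0.9):
            p = params.with_values({"prob_crash_hpv": prob})
            res = run_simulation([Strategy.HPV], p, cohort,
                                 n_iterations=2_000, seed=13)
            q = res.qalys[Strategy.HPV]
            if previous is not None:
                assert (q <= previous + 1e-9).all()
            previous = q

    def test_monte_carlo_error_shrinks_with_root_n(self, params, cohort):
        """SD of the mean cost over independent seeds falls by ~1/sqrt(2)
        when the iteration count doubles."""
        means = {400: [], 800: []}
        for n, out in means.items():
            for seed in range(40):
                res = run_simulation([Strategy.HPV], params, cohort,
                                     n_iterations=n, seed=1000 + seed)
                out.append(res.mean_cost(Strategy.HPV))
        ratio = np.std(means[800]) / np.std(means[400])
        assert 0.707 * 0.70 < ratio < 0.707 * 1.42


class TestAccountingIdentity:
    def test_replay_of_event_log_reproduces_costs_and_qalys(self, params, cohort):
        """Independent replay: rebuild each iteration's discounted totals
        from its state/crash event log alone and compare to the engine."""
        from avcea.costs import build_cost_schedule

        n = 1_000
        res = run_simulation([Strategy.AV], params, cohort,
                             n_iterations=n, seed=17, trace=True)
        sched = build_cost_schedule(Strategy.AV, params)
        c = params.constants
        tr = res.traces[Strategy.AV]
        T = c.n_timesteps
        df = (1 + c.discount_rate) ** -np.arange(T)
        util = {
            int(HealthState.DRIVING): c.healthy_utility,
            int(HealthState.DRIVING_INJURED): c.severe_injury_utility,
            int(HealthState.DEAD): 0.0,
            int(HealthState.POST_HORIZON_HEALTHY): c.healthy_utility,
            int(HealthState.POST_HORIZON_INJURED): c.severe_injury_utility,
        }
        for i in range(n):
            cost = sched.purchase
            qalys = 0.0
            for t in range(T):
                state = int(tr.states[i, t])
                qalys += util[state] * df[t]
                if state in (0, 1):
                    cost += sched.annual_recurring * df[t]
                sev = int(tr.crash_severity[i, t])
                if sev >= 0:
                    cost += sched.crash_costs[sev] * df[t]
                    if sev == 3:
                        cost += sched.funeral * df[t]
                died_now = (
                    state != int(HealthState.DEAD)
                    and int(tr.states[i, t + 1]) == int(HealthState.DEAD)
                )
                if died_now and sev != 3 and state in (0, 1):
                    cost += sched.funeral * df[t]  # lifetable death in horizon
            assert cost == pytest.approx(res.cost[Strategy.AV][i], rel=1e-10)
            assert qalys == pytest.approx(res.qalys[Strategy.AV][i], rel=1e-10)
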