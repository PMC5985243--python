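"""Paired Markov-chain Monte Carlo engine over annual timesteps.

Each iteration simulates drivers of a shared randomly drawn start age, one
per compared strategy, over T annual timesteps.  States: DRIVING,
DRIVING_INJURED (severe injury, permanent), DEAD (absorbing), and the two
post-analytic-horizon states entered when the vehicle leaves service
(quality-of-life accrual continues, vehicle costs stop).

Within a timestep, a subject alive at its start accrues that year's
discounted utility (by current state) and, while in a driving state, the
recurring vehicle costs; then a crash is resolved (fatal -> DEAD with
crash + funeral cost; severe -> DRIVING_INJURED; minor/PDO -> cost only),
then lifetable mortality by current age (funeral charged if the vehicle is
still in service), then vehicle expiration (driving states move to the
matching post-horizon state).  The purchase price is charged at t = 0
only.  QALYs use start-of-year discounting (year 0 undiscounted) and no
half-cycle correction.

Variance reduction: the start-age draw and all per-timestep uniform
streams (crash occurrence, crash severity, mortality, vehicle expiration)
are shared across every strategy of a run — full common random numbers —
so incremental costs and QALYs between strategies are estimated with far
smaller Monte Carlo error than the per-strategy levels, and two strategies
with identical inputs produce identical histories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

from .cohort import MAX_AGE, CohortTables, default_cohort
from .costs import CostSchedule, build_cost_schedule
from .crash import CrashProfile, crash_profile, outcomes_from_uniforms
from .parameters import ParameterSet
from .strategy import Strategy

__all__ = [
    "ArmTrace",
    "HealthState",
    "IterationRecord",
    "SimulationResult",
    "run_iteration",
    "run_simulation",
]


class HealthState(IntEnum):
    DRIVING = 0
    DRIVING_INJURED = 1
    DEAD = 2
    POST_HORIZON_HEALTHY = 3
    POST_HORIZON_INJURED = 4


_DRIVING_STATES = (HealthState.DRIVING, HealthState.DRIVING_INJURED)


@dataclass(frozen=True)
class ArmTrace:
    """Event-level history of one strategy arm (for audits and replay).

    ``states[:, t]`` is the state at the *start* of timestep t (one extra
    column holds the final state); ``crash_severity[:, t]`` is -1 for no
    crash, else the severity index resolved during t.
    """

    states: np.ndarray          # (n, T+1) int8
    crash_severity: np.ndarray  # (n, T) int8
    death_time: np.ndarray      # (n,) int32, -1 if censored
    expire_time: np.ndarray     # (n,) int32, -1 if the car outlived its use


@dataclass
class _Uniforms:
    crash: np.ndarray
    severity: np.ndarray
    mortality: np.ndarray
    expiration: np.ndarray


def _vehicle_hazard_by_year(cohort: CohortTables, n_timesteps: int) -> np.ndarray:
    """h[t] = P(car expires at vehicle age t | in service), t = 0..T."""
    h = np.ones(n_timesteps + 2)
    h[0] = 0.0
    table = cohort.vehicle_lifetable
    upto = min(len(table.expire_prob), n_timesteps + 1)
    h[1:upto + 1] = table.expire_prob[:upto]
    return h


def _simulate_arm(schedule: CostSchedule, profile: CrashProfile,
                  params: ParameterSet, cohort: CohortTables,
                  ages: np.ndarray, u: _Uniforms, trace: bool = False):
    """Vectorized simulation of one strategy arm over all iterations."""
    c = params.constants
    n = ages.size
    T = c.n_timesteps
    rate = c.discount_rate
    df = (1.0 + rate) ** -np.arange(T)
    utility = np.array([
        c.healthy_utility, c.severe_injury_utility, 0.0,
        c.healthy_utility, c.severe_injury_utility,
    ])
    q = cohort.mortality.q
    veh_h = _vehicle_hazard_by_year(cohort, T)

    state = np.full(n, HealthState.DRIVING, dtype=np.int8)
    age = ages.astype(np.int64).copy()
    cost = np.full(n, float(schedule.purchase))
    qalys = np.zeros(n)
    death_time = np.full(n, -1, dtype=np.int32)
    expire_time = np.full(n, -1, dtype=np.int32)

    if trace:
        states_h = np.empty((n, T + 1), dtype=np.int8)
        crash_h = np.full((n, T), -1, dtype=np.int8)

    recurring = schedule.annual_recurring
    crash_costs = schedule.crash_costs
    funeral = schedule.funeral

    for t in range(T):
        if trace:
            states_h[:, t] = state
        alive = state != HealthState.DEAD
        if not alive.any():
            if trace:
                states_h[:, t:] = state[:, None]
            break
        driving = (state == HealthState.DRIVING) | (
            state == HealthState.DRIVING_INJURED)

        # accrual for the year (subject alive at its start)
        qalys += np.where(alive, utility[state] * df[t], 0.0)
        cost += np.where(driving, recurring * df[t], 0.0)

        # 1) crash, while in a driving state
        outcome = outcomes_from_uniforms(
            profile, u.crash[:, t], u.severity[:, t])
        outcome = np.where(driving, outcome, -1)
        crashed = outcome >= 0
        if crashed.any():
            cost[crashed] += crash_costs[outcome[crashed]] * df[t]
            fatal = outcome == 3
            cost[fatal] += funeral * df[t]
            state[fatal] = HealthState.DEAD
            death_time[fatal] = t
            severe = (outcome == 2) & (state == HealthState.DRIVING)
            state[severe] = HealthState.DRIVING_INJURED
            if trace:
                crash_h[:, t] = outcome
        # 2) lifetable mortality by current age
        at_risk = state != HealthState.DEAD
        dies = at_risk & (u.mortality[:, t] < q[np.minimum(age, MAX_AGE)])
        in_horizon = (state == HealthState.DRIVING) | (
            state == HealthState.DRIVING_INJURED)
        cost[dies & in_horizon] += funeral * df[t]
        state[dies] = HealthState.DEAD
        death_time[dies] = t
        # 3) vehicle expiration (checked for the coming year)
        still_driving = (state == HealthState.DRIVING) | (
            state == HealthState.DRIVING_INJURED)
        expires = still_driving & (u.expiration[:, t] < veh_h[t + 1])
        expire_time[expires] = t
        state[expires & (state == HealthState.DRIVING)] = (
            HealthState.POST_HORIZON_HEALTHY)
        state[expires & (state == HealthState.DRIVING_INJURED)] = (
            HealthState.POST_HORIZON_INJURED)

        age += 1
    if trace:
        states_h[:, T] = state
        arm_trace = ArmTrace(states_h, crash_h, death_time, expire_time)
    else:
        arm_trace = None
    return cost, qalys, death_time, arm_trace


@dataclass
class SimulationResult:
    """Per-iteration paired outputs for every simulated strategy."""

    strategies: list
    ages: np.ndarray
    cost: dict
    qalys: dict
    death_time: dict
    seed: object = None
    traces: dict | None = None

    @property
    def n_iterations(self) -> int:
        return int(self.ages.size)

    def mean_cost(self, strategy) -> float:
        return float(self.cost[Strategy(strategy)].mean())

    def mean_qalys(self, strategy) -> float:
        return float(self.qalys[Strategy(strategy)].mean())

    def incremental(self, comparator, reference) -> tuple[float, float]:
        """Mean paired (delta cost, delta QALYs): comparator - reference."""
        comparator, reference = Strategy(comparator), Strategy(reference)
        dc = self.cost[comparator] - self.cost[reference]
        dq = self.qalys[comparator] - self.qalys[reference]
        return float(dc.mean()), float(dq.mean())

    def summary(self) -> pd.DataFrame:
        """Per-strategy means with empirical 2.5/97.5 percentile intervals."""
        rows = []
        for s in self.strategies:
            cost = self.cost[s]
            qalys = self.qalys[s]
            rows.append({
                "strategy": s.value,
                "mean_cost": cost.mean(),
                "cost_p2.5": np.percentile(cost, 2.5),
                "cost_p97.5": np.percentile(cost, 97.5),
                "mean_qalys": qalys.mean(),
                "qalys_p2.5": np.percentile(qalys, 2.5),
                "qalys_p97.5": np.percentile(qalys, 97.5),
            })
        return pd.DataFrame(rows)


def run_simulation(strategies, params: ParameterSet | None = None,
                   cohort: CohortTables | None = None,
                   n_iterations: int | None = None, seed=None,
                   trace: bool = False) -> SimulationResult:
    """Run the paired microsimulation for a list of strategies.

    All strategies share the start-age draw and every per-timestep uniform
    stream (common random numbers).  Bit-reproducible for a fixed seed.
    """
    params = params or ParameterSet.default()
    cohort = cohort or default_cohort()
    strategies = [Strategy(s) for s in strategies]
    if len(set(strategies)) != len(strategies):
        raise ValueError("duplicate strategies in run")
    c = params.constants
    n = int(n_iterations if n_iterations is not None else c.n_iterations)
    if n < 1:
        raise ValueError("n_iterations must be >= 1")
    T = c.n_timesteps

    rng = np.random.default_rng(seed)
    ages = cohort.age_distribution.sample(rng, size=n)
    u = _Uniforms(
        crash=rng.random((n, T)),
        severity=rng.random((n, T)),
        mortality=rng.random((n, T)),
        expiration=rng.random((n, T)),
    )

    cost, qalys, death_time, traces = {}, {}, {}, {}
    for s in strategies:
        schedule = build_cost_schedule(s, params)
        profile = crash_profile(s, params)
        co, qa, dt, tr = _simulate_arm(
            schedule, profile, params, cohort, ages, u, trace=trace)
        cost[s], qalys[s], death_time[s] = co, qa, dt
        if trace:
            traces[s] = tr

    return SimulationResult(
        strategies=strategies, ages=ages, cost=cost, qalys=qalys,
        death_time=death_time, seed=seed, traces=traces if trace else None,
    )


@dataclass(frozen=True)
class IterationRecord:
    """One paired iteration: shared start age, per-arm discounted totals."""

    start_age: int
    arms: dict  # Strategy -> dict(cost, qalys, death_time, crash_history)

    def arm(self, strategy):
        return self.arms[Strategy(strategy)]


def run_iteration(strategy_pair, params: ParameterSet | None = None,
                  cohort: CohortTables | None = None,
                  rng: np.random.Generator | None = None) -> IterationRecord:
    """Simulate a single paired iteration (both arms share all draws)."""
    rng = rng if rng is not None else np.random.default_rng()
    seed = int(rng.integers(2 ** 31))
    res = run_simulation(list(strategy_pair), params, cohort,
                         n_iterations=1, seed=seed, trace=True)
    arms = {}
    for s in res.strategies:
        tr = res.traces[s]
        history = [
            (t, int(sev))
            for t, sev in enumerate(tr.crash_severity[0])
            if sev >= 0
        ]
        dt = int(res.death_time[s][0])
        arms[s] = {
            "cost": float(res.cost[s][0]),
            "qalys": float(res.qalys[s][0]),
            "death_time": dt if dt >= 0 else None,
            "crash_history": history,
        }
    return IterationRecord(start_age=int(res.ages[0]), arms=arms)
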