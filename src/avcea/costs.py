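"""Dollar flows: purchase, recurring ownership costs, crash costs, discounting.

All amounts are 2016 US dollars.  A strategy's :class:`CostSchedule` has
four pieces: the one-off purchase price (charged at t = 0), the annual
recurring cost while the vehicle is in service (ownership and operation,
amortized parking, productivity loss from piloting, taxi-driver salary
where applicable), per-event crash costs by severity, and a one-off
funeral cost charged at fatal crash or at lifetable death while the
vehicle is still in service.

Structural choices
------------------
* Parking infrastructure is annuitized straight-line over 30 years at 0%
  real (jointly calibrated with the 15-year vehicle lifespan so the HPV
  lifetime cost matches its published point estimate).  Non-taxi vehicles
  carry ``spot cost x 3.4`` spots; taxis carry a single spot.
* Autonomous strategies pay an annual maintenance premium equal to
  ``av_maintenance_premium_rate`` (default 1%/yr) of the present-day AV
  equipment premium (AV price minus HPV price).  All three AV strategies
  carry the same sensing hardware, so the premium is identical across them
  even when the purchase price falls with Moore's law.
* Productivity loss applies only while a subject pilots a vehicle
  personally: the privately owned HPV.  AVs free the occupant; taxi
  passengers do not drive (the human taxi driver's time enters through the
  salary instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crash import CrashOutcome
from .parameters import ParameterSet
from .strategy import Strategy

__all__ = [
    "AvCostScaling",
    "CostSchedule",
    "DEFAULT_DAMAGE_SHARES",
    "amortize_parking",
    "build_cost_schedule",
    "derive_av_crash_costs",
    "discount",
    "moore_projection",
    "scale_crash_cost",
]


@dataclass(frozen=True)
class CostSchedule:
    """All dollar flows of one strategy."""

    strategy: Strategy
    purchase: float
    components: dict = field(default_factory=dict)
    crash_costs: np.ndarray = field(default_factory=lambda: np.zeros(4))
    funeral: float = 0.0

    def __post_init__(self) -> None:
        cc = np.asarray(self.crash_costs, dtype=float)
        object.__setattr__(self, "crash_costs", cc)
        amounts = [self.purchase, self.funeral, *self.components.values(), *cc]
        if any(a < 0 for a in amounts):
            raise ValueError("cost components must be non-negative")

    @property
    def annual_recurring(self) -> float:
        """Total recurring cost per year while the vehicle is in service."""
        return float(sum(self.components.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [("purchase", self.purchase)]
        rows += list(self.components.items())
        rows += [
            (f"crash_{s.name.lower()}", self.crash_costs[s])
            for s in (CrashOutcome.PDO, CrashOutcome.MINOR,
                      CrashOutcome.SEVERE, CrashOutcome.FATAL)
        ]
        rows.append(("funeral", self.funeral))
        return pd.DataFrame(rows, columns=["component", "amount"]).assign(
            strategy=self.strategy.value
        )


@dataclass(frozen=True)
class AvCostScaling:
    """Structure of the AV crash-cost uplift: the share of a crash's cost
    attributable to vehicle damage, scaled by the AV's price premium."""

    damage_share: float
    av_marginal_cost: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.damage_share <= 1.0):
            raise ValueError("damage_share must lie in [0, 1]")
        if self.av_marginal_cost < 0:
            raise ValueError("av_marginal_cost must be >= 0")


def discount(amount: float, t: float, rate: float) -> float:
    """Present value of ``amount`` accruing ``t`` years from the start."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be >= 0")
    return amount / (1.0 + rate) ** t


def moore_projection(cost_now: float, years: float, halving_period: float,
                     fixed_component: float = 0.0) -> float:
    """Project a technology cost forward under periodic halving.

    The non-technology part (``fixed_component``, e.g. the conventional
    vehicle underneath) keeps its price; the remainder halves every
    ``halving_period`` years.
    """
    if halving_period <= 0:
        raise ValueError("halving_period must be positive")
    if not (0.0 <= fixed_component <= cost_now):
        raise ValueError("require 0 <= fixed_component <= cost_now")
    return fixed_component + (cost_now - fixed_component) * 2.0 ** (
        -years / halving_period
    )


def amortize_parking(spot_cost: float, ratio: float, amortization_years: float,
                     rate: float = 0.0) -> float:
    """Annuitized parking cost per car-year.

    ``spot_cost x ratio`` is the capital tied up per registered car; it is
    spread over ``amortization_years`` with an annuity at ``rate`` (0 gives
    straight-line division).
    """
    if amortization_years <= 0:
        raise ValueError("amortization_years must be positive")
    capital = spot_cost * ratio
    if rate == 0.0:
        return capital / amortization_years
    return capital * rate / (1.0 - (1.0 + rate) ** (-amortization_years))


def scale_crash_cost(hpv_cost: float, scaling: AvCostScaling,
                     hpv_vehicle_cost: float, av_vehicle_cost: float) -> float:
    """Uplift a crash cost for the pricier AV hardware at risk.

    The vehicle-damage share of the crash cost scales with the AV/HPV price
    ratio: ``hpv_cost + damage_share * hpv_cost * (av/hpv - 1)`` (plus any
    explicit marginal cost).  Clamps at the HPV cost, with a warning, if
    the AV is somehow cheaper.
    """
    if min(hpv_cost, hpv_vehicle_cost, av_vehicle_cost) <= 0:
        raise ValueError("costs must be positive")
    if av_vehicle_cost < hpv_vehicle_cost:
        warnings.warn(
            "AV vehicle cheaper than HPV; crash-cost scaling clamped",
            stacklevel=2,
        )
    uplift = scaling.damage_share * hpv_cost * (
        av_vehicle_cost / hpv_vehicle_cost - 1.0
    )
    return max(hpv_cost, hpv_cost + uplift + scaling.av_marginal_cost)


# Per-severity vehicle-damage shares implied by the published HPV/AV crash
# cost pairs at the base vehicle prices: a validation of the uplift
# structure, not on the simulation's critical path (the published AV
# column is used directly there).
DEFAULT_DAMAGE_SHARES: dict[CrashOutcome, float] = {
    CrashOutcome.PDO: 0.019218,
    CrashOutcome.MINOR: 0.019188,
    CrashOutcome.SEVERE: 0.016310,
    CrashOutcome.FATAL: 0.003046,
}


def derive_av_crash_costs(params: ParameterSet | None = None) -> np.ndarray:
    """Re-derive the AV crash-cost column from the HPV column via
    :func:`scale_crash_cost` with the default damage shares (matches the
    published AV values within 1%)."""
    params = params or ParameterSet.default()
    hpv_price = params.value("cost_vehicle_hpv")
    av_price = params.value("cost_vehicle_av")
    out = []
    for sev, key in zip(
        (CrashOutcome.PDO, CrashOutcome.MINOR, CrashOutcome.SEVERE,
         CrashOutcome.FATAL),
        ("pdo", "minor", "severe", "fatal"),
    ):
        out.append(
            scale_crash_cost(
                params.value(f"crash_cost_{key}_hpv"),
                AvCostScaling(DEFAULT_DAMAGE_SHARES[sev]),
                hpv_price,
                av_price,
            )
        )
    return np.array(out)


_PURCHASE_PARAM = {
    Strategy.HPV: "cost_vehicle_hpv",
    Strategy.AV: "cost_vehicle_av",
    Strategy.AV_5YR: "cost_vehicle_av_5yr",
    Strategy.AV_TAXI: "cost_vehicle_taxi_av",
    Strategy.HPT: "cost_vehicle_taxi_hpv",
}


def build_cost_schedule(strategy: Strategy, params: ParameterSet | None = None
                        ) -> CostSchedule:
    """Assemble the full dollar-flow schedule for one strategy."""
    strategy = Strategy(strategy)
    params = params or ParameterSet.default()
    v = params.value

    purchase = v(_PURCHASE_PARAM[strategy])

    ownership = v("cost_ownership_annual")
    if strategy.is_autonomous:
        premium = max(0.0, v("cost_vehicle_av") - v("cost_vehicle_hpv"))
        ownership += v("av_maintenance_premium_rate") * premium

    years = v("parking_amortization_years")
    rate = v("parking_amortization_rate")
    if strategy.is_taxi:
        parking = amortize_parking(v("cost_parking_spot_taxi"), 1.0, years, rate)
    else:
        parking = amortize_parking(
            v("cost_parking_spot"), v("parking_spot_ratio"), years, rate
        )

    productivity = 0.0
    if strategy is Strategy.HPV:
        # published annual figure corresponds to the base productivity
        # parameter of 0.3; scale proportionally if that parameter moves
        productivity = v("cost_productivity_annual") * (
            v("productivity_fraction") / 0.3
        )

    salary = v("cost_taxi_salary") if strategy is Strategy.HPT else 0.0

    suffix = "av" if strategy.is_autonomous else "hpv"
    crash_costs = np.array([
        v(f"crash_cost_pdo_{suffix}"),
        v(f"crash_cost_minor_{suffix}"),
        v(f"crash_cost_severe_{suffix}"),
        v(f"crash_cost_fatal_{suffix}"),
    ])

    components = {
        "ownership": ownership,
        "parking": parking,
        "productivity": productivity,
        "salary": salary,
    }
    return CostSchedule(
        strategy=strategy,
        purchase=purchase,
        components=components,
        crash_costs=crash_costs,
        funeral=v("cost_funeral"),
    )
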