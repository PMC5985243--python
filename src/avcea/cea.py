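"""Decision metrics: ICERs, dominance, sensitivity analyses, WTP thresholds.

The incremental cost-effectiveness ratio (ICER) is the incremental change
in cost divided by the incremental change in QALYs between a comparator
strategy and a reference strategy.  A comparator that costs less and
yields more QALYs *dominates* ("saves money and QALYs"); one that costs
more and yields fewer QALYs is *dominated*.  A strategy is deemed
cost-effective at a willingness-to-pay (WTP) threshold when its ICER does
not exceed the threshold (boundary inclusive); in the southwest quadrant
(saves money, loses QALYs) the savings per QALY forgone must meet or
exceed the threshold instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTables, default_cohort
from .microsim import SimulationResult, run_simulation
from .parameters import ParameterSet, sample_psa
from .strategy import Strategy

__all__ = [
    "CEAResult",
    "PSAResult",
    "compute_icer",
    "one_way_sensitivity",
    "run_psa",
    "simulate_pair",
    "threshold_verdict",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"
ICER = "icer"


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of a comparator against a reference."""

    delta_cost: float
    delta_qalys: float
    icer: float | None
    verdict: str  # "icer" | "dominant" | "dominated" | "undefined"
    wtp_threshold: float | None = None

    @property
    def cost_effective(self) -> bool | None:
        if self.wtp_threshold is None:
            return None
        return threshold_verdict(self, self.wtp_threshold)


def compute_icer(delta_cost: float, delta_qalys: float,
                 wtp_threshold: float | None = None) -> CEAResult:
    """Classify an incremental (cost, QALY) pair.

    Zero QALY difference yields an undefined-ICER flag rather than an
    error; negative cost with positive QALYs is dominance (no ratio).
    """
    if delta_qalys == 0.0:
        return CEAResult(delta_cost, delta_qalys, None, UNDEFINED,
                         wtp_threshold)
    if delta_qalys > 0 and delta_cost < 0:
        return CEAResult(delta_cost, delta_qalys, None, DOMINANT,
                         wtp_threshold)
    if delta_qalys < 0 and delta_cost > 0:
        return CEAResult(delta_cost, delta_qalys, None, DOMINATED,
                         wtp_threshold)
    return CEAResult(delta_cost, delta_qalys, delta_cost / delta_qalys,
                     ICER, wtp_threshold)


def threshold_verdict(icer_or_result, wtp: float) -> bool:
    """True iff cost-effective at the WTP threshold (boundary inclusive)."""
    if isinstance(icer_or_result, CEAResult):
        r = icer_or_result
        if r.verdict == DOMINANT:
            return True
        if r.verdict == DOMINATED:
            return False
        if r.verdict == UNDEFINED:
            return r.delta_cost <= 0
        if r.delta_qalys < 0:  # southwest: savings per QALY forgone
            return r.icer >= wtp
        return r.icer <= wtp
    icer = float(icer_or_result)
    if math.isnan(icer):
        raise ValueError("ICER is undefined")
    return icer <= wtp


def simulate_pair(pair, params: ParameterSet | None = None,
                  cohort: CohortTables | None = None,
                  n_iterations: int | None = None, seed=None,
                  ) -> tuple[CEAResult, SimulationResult]:
    """Run the paired simulation for (reference, comparator) and compare.

    Returns the incremental result (comparator vs reference, evaluated at
    the configured WTP threshold) together with the raw simulation output.
    """
    reference, comparator = (Strategy(s) for s in pair)
    params = params or ParameterSet.default()
    res = run_simulation([reference, comparator], params, cohort,
                         n_iterations=n_iterations, seed=seed)
    dc, dq = res.incremental(comparator, reference)
    return compute_icer(dc, dq, params.constants.wtp_threshold), res


def one_way_sensitivity(pair, params: ParameterSet | None = None,
                        cohort: CohortTables | None = None,
                        parameters=None, n_iterations: int | None = None,
                        seed=0) -> pd.DataFrame:
    """One-way sensitivity analysis over parameters with published ranges.

    Each varied parameter is set to its low and high bound in turn (all
    others at base) and the paired simulation re-run with the *same* seed,
    so rows are deterministic and comparable.  Parameters without a proper
    range are skipped.  Returns one row per parameter with the ICER at
    each bound and the absolute swing.
    """
    params = params or ParameterSet.default()
    cohort = cohort or default_cohort()
    names = list(parameters) if parameters is not None else params.varied_names()
    rows = []
    for name in names:
        spec = params.spec(name)
        if spec.low >= spec.high:
            continue  # fixed parameter: nothing to vary
        results = {}
        for bound in ("low", "high"):
            value = getattr(spec, bound)
            p_mod = params.with_values({name: {"base": value}})
            cea, _ = simulate_pair(pair, p_mod, cohort,
                                   n_iterations=n_iterations, seed=seed)
            results[bound] = cea
        lo, hi = results["low"], results["high"]
        swing = (
            abs(hi.icer - lo.icer)
            if lo.icer is not None and hi.icer is not None
            else np.nan
        )
        rows.append({
            "parameter": name,
            "low": spec.low,
            "high": spec.high,
            "icer_at_low": lo.icer if lo.icer is not None else np.nan,
            "icer_at_high": hi.icer if hi.icer is not None else np.nan,
            "verdict_low": lo.verdict,
            "verdict_high": hi.verdict,
            "cost_effective_low": lo.cost_effective,
            "cost_effective_high": hi.cost_effective,
            "swing": swing,
        })
    return pd.DataFrame(rows)


@dataclass
class PSAResult:
    """Probabilistic sensitivity analysis output distribution."""

    draws: pd.DataFrame  # delta_cost, delta_qalys, icer, verdict, cost_effective
    wtp_threshold: float

    @property
    def prob_cost_effective(self) -> float:
        return float(self.draws["cost_effective"].mean())

    def acceptability(self, wtp) -> np.ndarray | float:
        """Fraction of draws cost-effective at the given WTP value(s)."""
        wtps = np.atleast_1d(np.asarray(wtp, dtype=float))
        out = np.empty(wtps.shape)
        for i, w in enumerate(wtps):
            flags = [
                threshold_verdict(
                    CEAResult(row.delta_cost, row.delta_qalys,
                              None if np.isnan(row.icer) else row.icer,
                              row.verdict), w)
                for row in self.draws.itertuples()
            ]
            out[i] = float(np.mean(flags))
        return out if np.ndim(wtp) else float(out[0])

    def acceptability_curve(self, wtp_grid) -> pd.DataFrame:
        grid = np.asarray(wtp_grid, dtype=float)
        return pd.DataFrame({
            "wtp": grid,
            "prob_cost_effective": self.acceptability(grid),
        })


def run_psa(pair, params: ParameterSet | None = None,
            cohort: CohortTables | None = None, n_draws: int = 200,
            inner_iterations: int = 1000, seed=0) -> PSAResult:
    """Probabilistic sensitivity analysis.

    Per draw, every parameter with a published range is sampled from its
    triangular distribution, then a reduced-size paired microsimulation is
    run (1,000 iterations by default for tractability; configurable) and
    the incremental result recorded.  Reproducible for a fixed seed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    params = params or ParameterSet.default()
    cohort = cohort or default_cohort()
    wtp = params.constants.wtp_threshold
    rng = np.random.default_rng(seed)
    # one shared inner seed: common random numbers across draws isolate
    # parameter uncertainty from microsimulation noise
    inner_seed = int(rng.integers(2 ** 31))
    rows = []
    for _ in range(n_draws):
        drawn = sample_psa(params, rng)
        cea, _ = simulate_pair(pair, drawn, cohort,
                               n_iterations=inner_iterations,
                               seed=inner_seed)
        rows.append({
            "delta_cost": cea.delta_cost,
            "delta_qalys": cea.delta_qalys,
            "icer": cea.icer if cea.icer is not None else np.nan,
            "verdict": cea.verdict,
            "cost_effective": threshold_verdict(cea, wtp),
        })
    return PSAResult(pd.DataFrame(rows), wtp)
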