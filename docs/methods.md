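# Methods

## Model structure

The engine (`avcea.microsim`) is a paired Markov-chain Monte Carlo
microsimulation.  One iteration draws a start age shared by all compared
strategies and walks each strategy's driver through `T = 100` annual
timesteps.  States: `DRIVING`, `DRIVING_INJURED` (permanent severe
injury), `DEAD` (absorbing), `POST_HORIZON_HEALTHY`, `POST_HORIZON_INJURED`
(car out of service; utility accrual continues, vehicle costs stop).

Within a timestep, for a subject alive at its start:

1. **Accrual.** The year's utility (by current state) and, in a driving
   state, the recurring vehicle costs, both discounted by `(1+r)^-t`
   (start-of-year discounting, year 0 undiscounted, no half-cycle
   correction).  The purchase price is charged at `t = 0`.
2. **Crash**, only in a driving state, with the strategy's annual
   probability; severity from the conditional split.  Fatal → `DEAD`
   (fatal crash cost + funeral); severe → `DRIVING_INJURED` (severe cost);
   minor/PDO → cost only.  At most one crash per year.
3. **Lifetable mortality** at the current integer age (crash survivors
   only; crash resolves first).  A funeral is charged if death occurs
   while the car is still in service.
4. **Vehicle expiration** for the coming year from the vehicle lifetable;
   driving states move to the matching post-horizon state.  The car is
   not replaced, and a non-fatal crash does not retire it (repair costs
   are inside the crash-cost figures).

The mortality table forces death at age 110, so with start ages ≤ 90
every subject is dead well before `t = 100`.

**Common random numbers.** The age draw and the four per-timestep uniform
streams (crash occurrence, severity, mortality, expiration) are shared
across all strategies of a run.  This is the standard paired-design
variance reduction: strategy *levels* carry the usual Monte Carlo error,
but *increments* between strategies are estimated far more precisely
(e.g. the AV−HPV QALY difference of ≈ +0.07 has an SE of ≈ 0.005 at
10,000 iterations under pairing, versus ≈ 0.1 unpaired).  It also makes
two strategies with identical inputs produce bitwise-identical histories.

## Parameters

All published inputs live in `avcea.parameters` with base values and,
where a range is published, triangular low/high bounds (2016 USD;
probabilities per driver-year).  Key constants: 3%/yr discount rate;
14,133 annual vehicle-miles per driver; productivity parameter 0.3
(the published $1,657/yr productivity loss corresponds to it and is
rescaled proportionally if the parameter moves); 3.4 parking spots per
registered non-taxi car; $140,000/QALY willingness-to-pay; 2-year
Moore's-law halving period for AV technology cost.

Structural parameters the published tables do not pin down, all exposed
in the registry:

| parameter | default | rationale |
|---|---|---|
| `healthy_utility` | 0.85 | EQ-5D-5L-style weight; calibrated jointly with the lifetable so HPV mean discounted QALYs ≈ 16.43 |
| `severe_injury_utility` | 0.60 | permanent severe injury weight |
| `parking_amortization_years` | 30 | straight-line at 0% real; typical parking-structure design life; calibrated jointly with vehicle lifespan to the ≈ $286k HPV lifetime cost |
| `vehicle_mean_lifespan` | 15 y | US average car service life |
| `vehicle_lifespan_shape` | 4.0 | Weibull shape; moderate dispersion around the mean |
| `av_maintenance_premium_rate` | 0.01 /yr | see below |
| `unreported_crash_multiplier` | 1.0 | optional scenario inflating the HPV crash probability for the ~47% of unreported crashes; off by default |

**AV ownership-cost scaling.** The annual cost of owning a car ($8,536)
is scaled up for autonomous strategies by an additive maintenance premium
of `av_maintenance_premium_rate × (AV price − HPV price)` — 1%/yr of the
present-day $150,000 equipment premium, i.e. +$1,500/yr.  The premium is
pegged to the *present-day* equipment premium for all three AV strategies
because they carry the same sensing hardware; the five-year projection
lowers the purchase price, not the hardware being serviced.  A
multiplicative scaling by the full price ratio (×5.46) was rejected: it
implies ≈ $46,600/yr ownership and AV lifetime costs near $790k,
irreconcilable with the AV cost structure this model is built to
reproduce.

**Severity splits.** The published splits carry rounding residue (the HPV
split sums to 1.0001); `CrashProfile` renormalizes every split to sum to
exactly 1 so sampling is well defined.  Sensitivity analyses perturb
split components individually; sums more than 5% from 1 are rejected as
malformed.

## Synthetic cohort

Three inputs have no published table; `avcea.cohort` generates them and
ships the defaults as CSV fixtures (regeneration is deterministic and
bit-identical — there is no randomness in the builders).

* **Driver ages**: piecewise-uniform over 5-year bands, 16–90, with
  band shares approximating the US licensed-driver age structure (mean
  ≈ 46.7 y).  Swappable for a real registry table via config.
* **Mortality**: Gompertz–Makeham hazard `λ + α e^{βa}` with λ = 5e-4,
  β = 0.096, closed at age 110.  α (= 3.32567e-5) was solved so that the
  mean 3%-discounted survival annuity over the age distribution, times
  the 0.85 healthy utility, equals 16.43 QALYs — the anchor value for the
  HPV arm.  The implied life expectancies (≈ 76 y at birth, ≈ 31.5 y at
  47) are slightly below the US 2016 period table; the calibration
  prioritizes the discounted-QALY anchor over unconditional longevity.
* **Vehicle lifespan**: discretized Weibull (shape 4), scale solved so
  the expected service life is exactly 15.0 years, closed at 31 years.

What the generator does *not* emulate: real driver-age/mortality
correlation with crash risk (crash probabilities are age-invariant, as in
the base analysis), cohort (non-period) mortality improvement, and the
much heavier-tailed vehicle-survival and utility assumptions that the
original TreeAge implementation appears to have used — its published 95%
intervals (e.g. HPV cost up to $653k, QALY lower bound 0.99) are wider
than this model's.  Passing tests therefore demonstrate reproduction of
*means* and incremental comparisons, not of the published interval
widths.

## Sensitivity analyses

* **One-way** (`one_way_sensitivity`): each bounded parameter in turn at
  its low and high value, all else at base, re-simulated with the *same*
  seed so rows differ only through the parameter.
* **PSA** (`run_psa`): each draw samples every bounded parameter from
  triangular(low, mode=base, high) (split components renormalized after
  sampling), then runs a reduced microsimulation — 1,000 iterations per
  draw by default, configurable.  A single inner seed is shared across
  draws (common random numbers again), so with all parameters frozen the
  draws are identical and the output distribution reflects parameter
  uncertainty only.  Cost-effectiveness at a threshold uses the standard
  quadrant rules (dominant → yes; dominated → no; northeast: ICER ≤ WTP,
  boundary inclusive; southwest: savings per QALY forgone ≥ WTP).

## Numerical choices and problem sizes

* Uniform streams are `numpy` PCG64 draws from a single seed; draw order
  (ages, then the four `(n, T)` uniform blocks) is fixed and documented,
  making every output bit-reproducible for a given seed.
* Severity sampling inverts the cumulative split via `searchsorted`; the
  ordering PDO < minor < severe < fatal makes severity regions nested
  across strategies under shared uniforms.
* Degenerate triangular ranges (low = high) return the base value
  exactly; zero discount rates degenerate to identity; zero-rate parking
  amortization degenerates to straight-line division.
* Default run sizes: 10,000 iterations for base-case tables (Monte Carlo
  SE of a strategy's mean cost ≈ $1k, of mean QALYs ≈ 0.07); 80,000
  paired iterations when a *verdict* about an ICER near the threshold is
  asserted, since the ICER is a ratio of two Monte Carlo means; 1,000
  inner iterations per PSA draw.

## Delta-V severity derivation

`severity_from_delta_v` maps a distribution of collision speed changes to
a severity split through a pluggable injury-risk curve, using the
KABCO↔MAIS correspondence (K→fatal, A→severe, B→minor, C/O→no injury).
The default `ExceedanceRiskCurve` uses nested saturating exceedance
functions `(v/c)^3 / (1+(v/c)^3)`; its three scales were calibrated so
that the expectation over a gamma ΔV distribution (shape 2, mean
3.91 mph) reproduces the published AV severity split.  It is a
provenance/calibration tool: the simulation consumes the published splits
directly, and the regression coefficients behind published ΔV risk
curves are not re-derived here.

## Known limitations

* The published AV annual crash probability (0.08385) is not exactly
  recoverable from the observed per-mile record (14 crashes / 2,102,047
  miles × 14,133 VMT gives 0.094 in product form, 0.0898 in complement
  form); the published value is taken as given, with both annualization
  conventions exposed.
* The published five-year AV price ($56,539) does not equal the Moore
  projection formula applied to the current price; the published value is
  used directly and `moore_projection` documents the structure.
* Taxi economics are reduced to the published cost rows (vehicle, salary,
  single parking spot); fares, profit margins, utilization, and the
  higher annual mileage of real taxis are out of scope, which is the main
  reason the AV-taxi mean cost sits ≈ 8% below its published point
  estimate (well within the reproduction tolerance).
* Crash risk does not vary with driver age or annual mileage, and
  vehicles carry a single occupant.
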