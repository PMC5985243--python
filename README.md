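# avcea — cost-effectiveness microsimulation of autonomous vehicles

`avcea` asks a health-economics question about a transport technology: at
today's prices and observed safety record, is an autonomous vehicle (AV) a
cost-effective alternative to a human-piloted vehicle (HPV) — as a family
car, and as a taxi?  It is written for health economists and
injury-prevention researchers who want a fully scripted, testable version
of a decision-analytic Markov microsimulation, with every input exposed in
a flat parameter registry.

## The model

Two drivers of the same randomly drawn age are followed in parallel, one
per strategy, over `T = 100` annual timesteps.  Each year a driver is in
one of five states — driving, driving severely injured, dead, or out of
the analytic horizon (the car's service life) healthy or injured.  While
driving, the subject pays the recurring costs of the strategy (ownership
and operation, amortized parking, productivity loss from piloting, taxi
salary where applicable) and faces an annual crash probability with a
conditional severity split over {property-damage-only, minor, severe,
fatal}; mortality follows a period lifetable; the car's expiration follows
a vehicle lifetable.  Costs and quality-adjusted life years (QALYs) are
discounted at 3% per year.  For strategies *i* (comparator) and *j*
(reference) the decision statistic is the incremental cost-effectiveness
ratio

ICER = (C_i − C_j) / (E_i − E_j)   [$ per QALY gained],

compared against a willingness-to-pay threshold of $140,000/QALY; a
comparator that saves both money and QALYs is *dominant*.  Five strategies
are built in: `HPV`, `AV` (today's price, $183,666), `AV_5YR` (price
projected five years out by Moore's-law halving, $56,539; identical
safety), `AV_TAXI`, and `HPT` (human-piloted taxi).  Parameter uncertainty
is handled by one-way sweeps over published low/high bounds and by a
probabilistic sensitivity analysis that samples every bounded parameter
from a triangular(low, mode = base, high) distribution.

Three inputs have no published table and are generated synthetically with
calibrated defaults shipped as CSV fixtures: the licensed-driver age
distribution (piecewise-uniform bands, mean ≈ 46.7 y), a Gompertz–Makeham
mortality lifetable, and a discretized-Weibull vehicle lifetable (mean
service life 15.0 y).  See `docs/methods.md` for the calibration targets
and every structural choice.

## Worked example

`examples/01_base_case.py` runs the paired microsimulation (10,000
iterations, common random numbers across strategies, seed 1) and prints:

```
strategy  mean_cost  cost_p2.5  cost_p97.5  mean_qalys  qalys_p2.5  qalys_p97.5
     HPV  286177.52   87904.77   413116.81       16.26        1.68        25.39
      AV  428062.51  237959.08   550210.96       16.33        1.68        25.39
  AV_5YR  300935.51  110832.08   423083.96       16.33        1.68        25.39
 AV_TAXI  410918.15  315776.59   473566.19       16.33        1.68        25.39
     HPT  555230.78  217299.06   770519.66       16.26        1.68        25.39

      AV vs HPV: Δcost $141,885, ΔQALY +0.066 -> $2,160,432/QALY
  AV_5YR vs HPV: Δcost $14,758, ΔQALY +0.066 -> $224,715/QALY
 AV_TAXI vs HPV: Δcost $124,741, ΔQALY +0.066 -> $1,899,381/QALY
 AV_TAXI vs HPT: Δcost $-144,313, ΔQALY +0.066 -> dominant
```

Reading: owning an HPV for the life of one car costs ≈ $286k discounted
and yields ≈ 16.3 discounted QALYs.  An AV adds a small, real safety gain
(+0.07 QALYs; it crashes 1.30× as often but almost never fatally) at a
price that makes it a poor health investment privately — even at the
5-year projected price the ICER stays above the $140,000/QALY threshold —
while the AV taxi *dominates* the human-piloted taxi: it saves money
(mostly the driver's salary) and QALYs at the same time.

The other examples cover the published-point-estimate ICER arithmetic
(`02`), crash-risk derivations and the delta-V severity curve (`03`),
one-way sensitivity (`04`), and the PSA acceptability curve (`05`).  A
thin CLI wraps the same pipeline:

```
avcea run --strategies HPV,AV --iterations 10000 --seed 1 --out out/
avcea sensitivity --mode psa --pair HPV,AV_5YR --draws 200 --out out/
```

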