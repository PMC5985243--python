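"""Crash-risk derivations: relative risks, annualization, delta-V severity.

Shows the headline safety contrasts (AVs crash more often but almost never
fatally), how a per-mile crash rate annualizes at 14,133 miles/year, and
how a distribution of collision speed changes maps to a severity split
through the calibrated injury-risk curve.
"""

import numpy as np

from avcea import ParameterSet, per_mile_to_annual, relative_risk, \
    severity_from_delta_v
from avcea.crash import WaymoSummary, default_delta_v_distribution

p = ParameterSet.default()
rr = relative_risk(p["prob_crash_av"], p["prob_crash_hpv"])
rr_fatal = relative_risk(p["prob_crash_av"] * p["split_fatal_av"],
                         p["prob_crash_hpv"] * p["split_fatal_hpv"])
print(f"RR of any crash, AV vs HPV:    {rr:.2f}")
print(f"RR of annual fatality:         {rr_fatal:.2f}")

w = WaymoSummary()
print(f"\nObserved AV record: {w.observed_crashes} crashes in "
      f"{w.miles:,} miles (mean ΔV {w.mean_delta_v} mph)")
for form in ("complement", "product"):
    annual = per_mile_to_annual(w.crashes_per_mile, p["annual_vmt"], form=form)
    print(f"  annualized ({form:>10}): {annual:.4f}")
print(f"  published base value used by the model: {p['prob_crash_av']}")

split = severity_from_delta_v(default_delta_v_distribution())
labels = ("PDO", "minor", "severe", "fatal")
print("\nSeverity split implied by the ΔV distribution (mean 3.91 mph):")
for name, value in zip(labels, split):
    print(f"  {name:>7}: {value:.3e}")
print("\nAVs crash ~1.3x as often, but collisions at ~4 mph are almost")
print("never fatal — the fatality relative risk is two orders smaller.")
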