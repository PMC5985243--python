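"""ICER arithmetic on the published summary table's point estimates.

Feeds the published lifetime cost and QALY point estimates through the
ICER classifier: three comparisons against the human-piloted vehicle give
dollars-per-QALY figures, while the taxi head-to-head is dominant (the AV
taxi saves both money and QALYs).
"""

from avcea import compute_icer, threshold_verdict

HPV = (286_146, 16.41)
cases = {
    "AV today": (425_757, 16.51),
    "AV in 5 years": (303_535, 16.51),
    "AV taxi": (447_667, 16.51),
}

for label, (cost, qalys) in cases.items():
    r = compute_icer(cost - HPV[0], round(qalys - HPV[1], 2))
    ce = threshold_verdict(r, 140_000)
    print(f"{label:>14}: ICER ${r.icer:,.0f}/QALY gained"
          f"  (cost-effective at $140k/QALY: {ce})")

r = compute_icer(447_667 - 570_032, round(16.51 - 16.41, 2))
print(f"{'AV taxi vs HPT':>14}: {r.verdict} (saves money and QALYs)")
print()
print("An ICER is the extra dollars paid per extra quality-adjusted life")
print("year; only the AV taxi is an unambiguous win at today's prices.")
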