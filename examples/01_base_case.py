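"""Base case: lifetime costs and QALYs of every strategy, with ICERs.

Runs the paired microsimulation (10,000 iterations, shared random streams
across strategies) at the base-case parameters and prints a summary table
plus the incremental cost-effectiveness of each strategy against the
privately owned human-piloted vehicle.
"""

from avcea import Strategy, compute_icer, run_simulation

strategies = [Strategy.HPV, Strategy.AV, Strategy.AV_5YR, Strategy.AV_TAXI,
              Strategy.HPT]
res = run_simulation(strategies, n_iterations=10_000, seed=1)

print(res.summary().round(2).to_string(index=False))
print()
for s in (Strategy.AV, Strategy.AV_5YR, Strategy.AV_TAXI):
    dc, dq = res.incremental(s, Strategy.HPV)
    cea = compute_icer(dc, dq, wtp_threshold=140_000)
    icer = f"${cea.icer:,.0f}/QALY" if cea.icer is not None else cea.verdict
    print(f"{s.value:>8} vs HPV: Δcost ${dc:,.0f}, ΔQALY {dq:+.3f} -> {icer}")

dc, dq = res.incremental(Strategy.AV_TAXI, Strategy.HPT)
cea = compute_icer(dc, dq)
print(f" AV_TAXI vs HPT: Δcost ${dc:,.0f}, ΔQALY {dq:+.3f} -> {cea.verdict}")
print()
print("Mean lifetime discounted cost and QALYs per strategy; a positive")
print("ΔQALY with a large ICER means the safety gain is real but expensive;")
print("'dominant' means the comparator saves both money and QALYs.")
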