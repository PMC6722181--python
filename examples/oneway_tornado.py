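"""One-way deterministic sensitivity analysis (tornado data).

Sweeps each chance node over its uncertainty interval, and the annual
national scan volume over 5,063-6,189 (which moves the per-patient
cost along the anchored piecewise-linear curve), recomputing the ICER
at every endpoint.
"""

from fetcea import builtin_table1, classify_cohort, estimate_chance_nodes, sweep, tornado_extrema

classified = classify_cohort(builtin_table1())

for endpoint in ("os", "pfs"):
    nodes = estimate_chance_nodes(classified, endpoint)
    rows = sweep(nodes)
    print(f"\nendpoint {endpoint.upper()}  (ICER in EUR per identified non-responder)")
    print(f"{'parameter':>14} {'low':>10} {'high':>10} {'icer_low':>10} {'icer_high':>10}")
    for r in rows:
        print(f"{r.parameter:>14} {r.low:>10.4f} {r.high:>10.4f} "
              f"{r.icer_at_low:>10.2f} {r.icer_at_high:>10.2f}")
    lo, hi = tornado_extrema(rows)
    print(f"  ICER range across all sweeps: {lo:,.2f} - {hi:,.2f} EUR")

# A wide bar means the conclusion is sensitive to that parameter; the
# call probabilities N1/N2 dominate because their intervals are widest.
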