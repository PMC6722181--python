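"""Base-case incremental cost-effectiveness ratios.

Prices the two-scan PET follow-up at the fixed per-patient cost of
780.50 EUR and divides by the PET-minus-MRI effectiveness increments.
"""

from fetcea import builtin_table1, classify_cohort, full_cea

classified = classify_cohort(builtin_table1())

for endpoint in ("os", "pfs"):
    result = full_cea(classified, endpoint)
    print(f"endpoint {endpoint.upper()}: cost {result.cost:.2f} EUR")
    print(f"  ICER per identified non-responder: "
          f"{result.icer_per_nonresponder:,.2f} EUR (delta = {result.delta_nr:.4f})")
    print(f"  ICER per correct diagnosis:        "
          f"{result.icer_per_diagnosis:,.2f} EUR (delta = {result.delta_accuracy:.4f})")

# Each euro figure is the extra spend needed for one additional
# correctly flagged non-responder (or one additional correct call)
# when adding PET to the follow-up protocol.
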