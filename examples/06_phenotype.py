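"""Summarize cold-injury phenotypes: electrolyte leakage index and recovery.

ELI is mean stress leakage over mean control leakage; ELI > 1 with a
one-sided t-test at p < 0.05 flags significant injury.  Recovery fractions
map to the 0-10 standard evaluation score by half-up rounding.
"""

import pandas as pd

from coldregulon import phenotype_table

leakage = pd.DataFrame(
    [
        dict(accession=acc, condition=cond, replicate=r, conductivity=v)
        for acc, cond, values in [
            ("tolerant-ref", "control", [0.20, 0.22, 0.19, 0.21, 0.20, 0.21]),
            ("tolerant-ref", "stress", [0.22, 0.21, 0.23, 0.20, 0.22, 0.21]),
            ("sensitive-check", "control", [0.21, 0.20, 0.22, 0.19, 0.21, 0.20]),
            ("sensitive-check", "stress", [0.55, 0.60, 0.58, 0.62, 0.57, 0.59]),
        ]
        for r, v in enumerate(values, start=1)
    ]
)
recovery = pd.DataFrame(
    [
        dict(accession="tolerant-ref", recovery_fraction=0.85),
        dict(accession="sensitive-check", recovery_fraction=0.15),
    ]
)

table = phenotype_table(leakage, recovery)
print(table.to_string(index=False))
# The sensitive accession shows ELI ~2.9 with a significant injury flag and
# a low recovery score; the tolerant reference stays near ELI 1 and scores 9.
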