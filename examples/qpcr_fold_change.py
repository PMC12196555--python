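"""Relative expression and percent-change utilities.

Computes 2^-ddCt fold changes from a long-format Ct table (normalized to
a reference gene, relative to a calibrator sample) and the percent-change
descriptor used for fruit morphometrics.
"""

import pandas as pd

from zfnkit import percent_change
from zfnkit.quant import fold_change_table

ct = pd.DataFrame(
    [
        # technical replicates per (sample, gene)
        ("WT",  "EF1a", 18.1), ("WT",  "EF1a", 17.9),
        ("WT",  "CHS2", 24.0), ("WT",  "CHS2", 24.2),
        ("mut", "EF1a", 18.0), ("mut", "EF1a", 18.2),
        ("mut", "CHS2", 22.1), ("mut", "CHS2", 21.9),
    ],
    columns=["sample", "gene", "ct"],
)

out = fold_change_table(ct, calibrator_sample="WT", reference_gene="EF1a")
print(out.to_string(index=False))
# CHS2 reaches threshold ~2 cycles earlier in the mutant relative to the
# EF1a-normalized calibrator, i.e. ~4-fold higher expression.

area_mut, area_wt = 16.3, 10.0
print(f"\nfruit area change: {percent_change(area_mut, area_wt):.0f}%")
# (m - wt)/wt x 100: a 63% increase over the wild-type value.
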