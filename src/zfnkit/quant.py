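"""Small quantification utilities: qPCR fold change and percent change.

Relative expression is computed by the 2^-ddCt method: the cycle
threshold (Ct) of the target gene is normalized to a reference gene
within each sample (dCt), the calibrator sample's dCt is subtracted
(ddCt), and fold change is 2**-ddCt.  No amplification-efficiency
correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["CtQuartet", "ddct_fold_change", "percent_change", "fold_change_table"]


@dataclass(frozen=True)
class CtQuartet:
    """Ct values for (target, reference) x (sample, calibrator)."""

    ct_target_sample: float
    ct_reference_sample: float
    ct_target_calibrator: float
    ct_reference_calibrator: float

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")


def ddct_fold_change(q: CtQuartet) -> float:
    """Fold change 2**-ddCt relative to the calibrator sample."""
    ddct = (q.ct_target_sample - q.ct_reference_sample) - (
        q.ct_target_calibrator - q.ct_reference_calibrator
    )
    return 2.0 ** (-ddct)


def percent_change(m: float, wt: float) -> float:
    """Percent change of a mutant measurement vs wild type: (m - wt)/wt x 100."""
    if wt == 0:
        raise ValueError("wild-type value must be non-zero")
    return (m - wt) / wt * 100.0


def fold_change_table(
    ct_long: pd.DataFrame,
    calibrator_sample: str,
    reference_gene: str,
) -> pd.DataFrame:
    """Fold changes from a long-format Ct table.

    ``ct_long`` has columns (sample, gene, ct); technical replicates are
    averaged before dCt.  Returns a (sample, gene, fold_change) table for
    every target gene in every sample, relative to the calibrator.
    """
    required = {"sample", "gene", "ct"}
    if not required <= set(ct_long.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    means = ct_long.groupby(["sample", "gene"], sort=True)["ct"].mean()
    if calibrator_sample not in means.index.get_level_values("sample"):
        raise ValueError(f"calibrator sample {calibrator_sample!r} not in table")
    rows = []
    for (sample, gene), ct in means.items():
        if gene == reference_gene:
            continue
        try:
            q = CtQuartet(
                ct_target_sample=ct,
                ct_reference_sample=means[(sample, reference_gene)],
                ct_target_calibrator=means[(calibrator_sample, gene)],
                ct_reference_calibrator=means[(calibrator_sample, reference_gene)],
            )
        except KeyError as exc:
            raise ValueError(f"missing Ct for {exc} needed by ({sample}, {gene})") from exc
        rows.append(dict(sample=sample, gene=gene, fold_change=ddct_fold_change(q)))
    return pd.DataFrame(rows, columns=["sample", "gene", "fold_change"])
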