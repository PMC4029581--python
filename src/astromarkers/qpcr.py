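"""Comparative-CT (delta-delta-Ct) quantification and field-count statistics.

qPCR fold changes assume 100% amplification efficiency (a doubling per
cycle): per condition, dCt = mean Ct(target) - mean Ct(reference);
relative to the control condition, ddCt = dCt(condition) - dCt(control)
and fold = 2^(-ddCt).  The immuno-quantification helpers convert
positive-cell counts per field of view into percentages and compare two
treatment groups with a two-tailed t test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtTable",
    "read_ct_table",
    "ddct_fold_change",
    "FieldCounts",
    "percent_positive",
    "two_group_ttest",
]


@dataclass
class CtTable:
    """Long-format qPCR records: one row per (gene, condition, replicate)."""

    records: pd.DataFrame  # columns: gene, condition, replicate, ct

    def __post_init__(self) -> None:
        required = {"gene", "condition", "replicate", "ct"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"Ct table missing column(s): {sorted(missing)}")
        if (self.records["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")

    @property
    def genes(self) -> list[str]:
        return sorted(self.records["gene"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.records["condition"].unique())


def read_ct_table(path: str | Path) -> CtTable:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    return CtTable(df)


def ddct_fold_change(
    ct: CtTable, reference_gene: str, control_condition: str
) -> pd.DataFrame:
    """Per-gene, per-condition fold change by the comparative-CT method.

    Replicate Ct values are averaged per (gene, condition) before any
    differencing.  The control condition's fold is exactly 1 for every
    gene.  Returns a genes x conditions DataFrame (reference gene
    excluded).
    """
    mean_ct = ct.records.groupby(["gene", "condition"])["ct"].mean().unstack("condition")
    if reference_gene not in mean_ct.index:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    if control_condition not in mean_ct.columns:
        raise ValueError(f"control condition {control_condition!r} absent from table")
    ref = mean_ct.loc[reference_gene]
    missing_ref = ref.index[ref.isna()].tolist()
    if missing_ref:
        raise ValueError(f"reference gene missing in condition(s): {missing_ref}")
    dct = mean_ct.drop(index=reference_gene).sub(ref, axis=1)
    ddct = dct.sub(dct[control_condition], axis=0)
    return 2.0 ** (-ddct)


@dataclass
class FieldCounts:
    """Positive / total cell counts over several fields of view for one group."""

    group: str
    counts: tuple[tuple[int, int], ...]  # (positive, total) per field

    def __post_init__(self) -> None:
        if len(self.counts) < 2:
            raise ValueError("need at least 2 fields of view")
        for pos, tot in self.counts:
            if pos < 0 or tot < 0 or pos != int(pos) or tot != int(tot):
                raise ValueError("counts must be nonnegative integers")
            if tot == 0:
                raise ValueError(f"field with zero total cells in group {self.group!r}")
            if pos > tot:
                raise ValueError("positive count exceeds total")


def percent_positive(counts: FieldCounts) -> tuple[float, np.ndarray]:
    """(group mean percentage, per-field percentages)."""
    per_field = np.array([100.0 * p / t for p, t in counts.counts])
    return float(per_field.mean()), per_field


def two_group_ttest(
    group1: Sequence[float],
    group2: Sequence[float],
    variant: Literal["student", "welch"] = "student",
) -> tuple[float, float]:
    """Two-tailed t test on per-field percentages; returns (t, p).

    "student" pools variances (df = n1 + n2 - 2); "welch" uses the
    Welch–Satterthwaite degrees of freedom.
    """
    g1, g2 = np.asarray(group1, float), np.asarray(group2, float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("need at least 2 observations per group")
    if g1.std(ddof=1) == 0 and g2.std(ddof=1) == 0:
        raise ValueError("both groups have zero variance; t test undefined")
    res = stats.ttest_ind(g1, g2, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)
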