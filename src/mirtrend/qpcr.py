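"""Relative qPCR quantification by the 2^-ddCt method.

dCt = mean Ct(target) - mean Ct(references) within a condition (with several
reference assays, the arithmetic mean of their Ct means, equivalent to the
geometric mean of their linear quantities); ddCt = dCt(condition) -
dCt(calibrator); fold change = 2^-ddCt, so the calibrator condition has fold
change 1 by construction.  Statistical comparison between conditions is
performed on per-sample dCt values (approximately normal), not on the
log-normal fold changes.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtTable",
    "FcComparison",
    "delta_delta_ct",
    "compare_fc",
    "DeltaDeltaCtModel",
    "DeltaDeltaCtResults",
]

_COLUMNS = ["sample_id", "condition", "assay", "replicate", "ct"]


@dataclass
class CtTable:
    """Long-format cycle-threshold table.

    One row per (sample, condition, assay, replicate) with the measured Ct in
    cycles; Ct values must be positive and finite.
    """

    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct table missing columns: {missing}")
        self.data = self.data[_COLUMNS].copy()
        ct = self.data["ct"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
            raise ValueError("Ct values must be positive and finite")
        by_sample = self.data.groupby("sample_id")["condition"].nunique()
        if (by_sample > 1).any():
            bad = by_sample.index[by_sample > 1][0]
            raise ValueError(f"sample {bad!r} appears under more than one condition")

    @property
    def conditions(self) -> list:
        return list(dict.fromkeys(self.data["condition"]))

    @property
    def assays(self) -> list:
        return list(dict.fromkeys(self.data["assay"]))

    def sample_mean_ct(self) -> pd.DataFrame:
        """Mean Ct per (condition, sample, assay) - replicate aggregation."""
        return (
            self.data.groupby(["condition", "sample_id", "assay"])["ct"].mean().reset_index()
        )


def _condition_delta_ct(table: CtTable, target_assay: str, reference_assays: Sequence[str]) -> pd.Series:
    """dCt per condition from per-sample mean Cts."""
    agg = table.sample_mean_ct()
    out = {}
    for cond, sub in agg.groupby("condition"):
        assay_means = sub.groupby("assay")["ct"].mean()
        for assay in [target_assay, *reference_assays]:
            if assay not in assay_means.index:
                raise ValueError(f"assay {assay!r} missing in condition {cond!r}")
        ref = assay_means.loc[list(reference_assays)].mean()
        out[cond] = assay_means.loc[target_assay] - ref
    return pd.Series(out, name="delta_ct")


def delta_delta_ct(
    table: CtTable,
    target_assay: str,
    reference_assays: str | Sequence[str],
    calibrator_condition: str,
) -> pd.DataFrame:
    """Relative expression (fold change) of the target per condition.

    Returns a frame indexed by condition with columns ``delta_ct``,
    ``delta_delta_ct`` and ``fold_change``; the calibrator row has fold
    change 1 by construction.
    """
    if isinstance(reference_assays, str):
        reference_assays = [reference_assays]
    if calibrator_condition not in table.conditions:
        raise ValueError(f"calibrator condition {calibrator_condition!r} not in table")
    dct = _condition_delta_ct(table, target_assay, reference_assays)
    ddct = dct - dct.loc[calibrator_condition]
    return pd.DataFrame(
        {
            "delta_ct": dct,
            "delta_delta_ct": ddct,
            "fold_change": 2.0 ** (-ddct),
        }
    )


def _per_sample_delta_ct(
    table: CtTable, condition: str, target_assay: str, reference_assays: Sequence[str]
) -> np.ndarray:
    agg = table.sample_mean_ct()
    sub = agg[agg["condition"] == condition]
    if sub.empty:
        raise ValueError(f"condition {condition!r} not in table")
    out = []
    for sid, s in sub.groupby("sample_id"):
        means = s.set_index("assay")["ct"]
        for assay in [target_assay, *reference_assays]:
            if assay not in means.index:
                raise ValueError(f"assay {assay!r} missing for sample {sid!r} in condition {condition!r}")
        out.append(means.loc[target_assay] - means.loc[list(reference_assays)].mean())
    return np.array(out)


@dataclass(frozen=True)
class FcComparison:
    group_a: str
    group_b: str
    fold_change: float  # of group_b relative to group_a
    p_value: float
    mean_delta_ct_a: float
    mean_delta_ct_b: float


def compare_fc(
    table: CtTable,
    groups: tuple[str, str],
    target_assay: str,
    reference_assays: str | Sequence[str],
) -> FcComparison:
    """Fold change between two conditions with an unpaired Student t-test
    on the per-sample dCt values.

    With zero variance in both groups the p-value is 0 for different means
    and 1 for equal means (degenerate-limit convention).
    """
    if isinstance(reference_assays, str):
        reference_assays = [reference_assays]
    ga, gb = groups
    a = _per_sample_delta_ct(table, ga, target_assay, reference_assays)
    b = _per_sample_delta_ct(table, gb, target_assay, reference_assays)
    if a.size < 2 or b.size < 2:
        raise ValueError("each condition needs >= 2 samples to compare fold changes")
    if a.std() == 0 and b.std() == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b).pvalue)
    return FcComparison(
        group_a=ga,
        group_b=gb,
        fold_change=float(2.0 ** (-(b.mean() - a.mean()))),
        p_value=p,
        mean_delta_ct_a=float(a.mean()),
        mean_delta_ct_b=float(b.mean()),
    )


class DeltaDeltaCtModel:
    """Relative-quantification model over a Ct table.

    Parameters are the target assay, one or more reference assays, and the
    calibrator condition; ``fit`` computes per-condition fold changes and,
    for two-condition designs, the dCt t-test against the calibrator.
    """

    def __init__(
        self,
        table: CtTable,
        target_assay: str,
        reference_assays: str | Sequence[str],
        calibrator_condition: str,
    ):
        self.table = table
        self.target_assay = target_assay
        self.reference_assays = (
            [reference_assays] if isinstance(reference_assays, str) else list(reference_assays)
        )
        self.calibrator_condition = calibrator_condition

    def fit(self) -> "DeltaDeltaCtResults":
        per_condition = delta_delta_ct(
            self.table, self.target_assay, self.reference_assays, self.calibrator_condition
        )
        comparisons = []
        for cond in per_condition.index:
            if cond == self.calibrator_condition:
                continue
            try:
                comparisons.append(
                    compare_fc(
                        self.table,
                        (self.calibrator_condition, cond),
                        self.target_assay,
                        self.reference_assays,
                    )
                )
            except ValueError:
                pass  # single-sample conditions: fold change only, no test
        return DeltaDeltaCtResults(model=self, per_condition=per_condition, comparisons=comparisons)


@dataclass
class DeltaDeltaCtResults:
    model: DeltaDeltaCtModel
    per_condition: pd.DataFrame
    comparisons: list[FcComparison]

    def summary(self) -> pd.DataFrame:
        out = self.per_condition.copy()
        pvals = {c.group_b: c.p_value for c in self.comparisons}
        out["p_value_vs_calibrator"] = [pvals.get(c, np.nan) for c in out.index]
        return out
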